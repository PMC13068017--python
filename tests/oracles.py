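"""Independent brute-force oracles used by the morphology and star-operation
tests.  These deliberately re-derive the definitions with plain loops /
symbolic algebra and share no code with the implementation they check."""
from __future__ import annotations

import numpy as np


def erode_core_bruteforce(f: np.ndarray, k: np.ndarray) -> np.ndarray:
    """min_m f(n+m) - k(m) for n = 0..N-M, by explicit scan."""
    n, m = len(f), len(k)
    return np.array([min(f[i + j] - k[j] for j in range(m)) for i in range(n - m + 1)])


def dilate_core_bruteforce(f: np.ndarray, k: np.ndarray) -> np.ndarray:
    """max_m f(n-m) + k(m) for n = M-1..N-1, by explicit scan."""
    n, m = len(f), len(k)
    return np.array([max(f[i - j] + k[j] for j in range(m)) for i in range(m - 1, n)])


def pad_left_constant(core: np.ndarray, total: int) -> np.ndarray:
    return np.concatenate([np.full(total - len(core), core[0]), core])


def pad_right_constant(core: np.ndarray, total: int) -> np.ndarray:
    return np.concatenate([core, np.full(total - len(core), core[-1])])


def erode_bruteforce(f: np.ndarray, k: np.ndarray) -> np.ndarray:
    return pad_right_constant(erode_core_bruteforce(f, k), len(f))


def dilate_bruteforce(f: np.ndarray, k: np.ndarray) -> np.ndarray:
    return pad_left_constant(dilate_core_bruteforce(f, k), len(f))


def open_bruteforce(f: np.ndarray, k: np.ndarray) -> np.ndarray:
    return dilate_bruteforce(erode_bruteforce(f, k), k)


def close_bruteforce(f: np.ndarray, k: np.ndarray) -> np.ndarray:
    return erode_bruteforce(dilate_bruteforce(f, k), k)


def star_monomial_count_symbolic(d: int) -> int:
    """Count distinct monomials in (w1ᵀx̃)(w2ᵀx̃) for x̃ = [x1..xd, 1] by
    symbolic expansion with sympy."""
    import sympy

    xs = sympy.symbols(f"x1:{d + 2}")  # x_{d+1} plays the role of the constant 1
    w1 = sympy.symbols(f"a1:{d + 2}")
    w2 = sympy.symbols(f"b1:{d + 2}")
    expr = sympy.expand(
        sum(a * x for a, x in zip(w1, xs)) * sum(b * x for b, x in zip(w2, xs))
    )
    monomials = set()
    for term in expr.as_ordered_terms():
        powers = term.as_powers_dict()
        mono = tuple(sorted(
            (str(sym), int(p)) for sym, p in powers.items() if sym in xs
        ))
        monomials.add(mono)
    return len(monomials)
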