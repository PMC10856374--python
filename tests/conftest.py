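import numpy as np
import pytest

from lpxnmr import build_default_library, default_grid


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def lib(grid):
    return build_default_library(grid)


@pytest.fixture(scope="session")
def serum_amplitudes():
    from lpxnmr import DEFAULT_SERUM_AMPLITUDES

    return dict(DEFAULT_SERUM_AMPLITUDES)


def nnls_support_oracle(design: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Exhaustive active-set oracle for small NNLS instances.

    Enumerates every support set, solves the unconstrained least squares on
    that support, keeps feasible candidates (all entries ≥ 0) and returns the
    one with the smallest residual norm.  Exponential in the number of
    columns — usable only for ≤ ~10 components.
    """
    from itertools import combinations

    n = design.shape[1]
    best_x = np.zeros(n)
    best_r = float(np.linalg.norm(target))
    for k in range(1, n + 1):
        for support in combinations(range(n), k):
            sub = design[:, support]
            coef, *_ = np.linalg.lstsq(sub, target, rcond=None)
            if np.any(coef < -1e-12):
                continue
            x = np.zeros(n)
            x[list(support)] = np.maximum(coef, 0.0)
            r = float(np.linalg.norm(design @ x - target))
            if r < best_r - 1e-13:
                best_r = r
                best_x = x
    return best_x
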