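import numpy as np
import pytest

import screenclean as sc


@pytest.fixture(scope="session")
def fixture_screen():
    """The 60-guide worked miniature: (library, counts, truth)."""
    return sc.worked_fixture()


@pytest.fixture(scope="session")
def fixture_result(fixture_screen):
    """Full pipeline output on the worked miniature."""
    library, counts, _ = fixture_screen
    return sc.correct_screen(library, counts, cbs_params=sc.CbsParams(seed=11))


@pytest.fixture(scope="session")
def small_screen():
    """A fast three-chromosome screen with one planted bias region."""
    cfg = sc.SimulationConfig(
        n_genes=300,
        n_chromosomes=3,
        bias_regions=(sc.BiasRegion(chrom_index=1, start_gene=30, n_genes=30, shift=-2.0),),
        noise_sd=0.2,
        seed=5,
    )
    return sc.simulate_screen(cfg), cfg


def brute_force_max_arc(values, min_width=2):
    """Independent exhaustive scan for the maximal-|t| arc.

    Computes the pooled-variance two-sample t for every arc ``(i, j]`` whose
    width and complement are both >= ``min_width``, with plain Python/numpy.
    Returns (i, j, max |t|).
    """
    x = np.asarray(values, dtype=float)
    m = len(x)
    best = (None, None, 0.0)
    for i in range(m):
        for j in range(i + 1, m + 1):
            k = j - i
            if k < min_width or m - k < min_width:
                continue
            arc = x[i:j]
            comp = np.concatenate([x[:i], x[j:]])
            ssw = ((arc - arc.mean()) ** 2).sum() + ((comp - comp.mean()) ** 2).sum()
            d = arc.mean() - comp.mean()
            if ssw > 0 and m > 2:
                t = abs(d) / np.sqrt(ssw / (m - 2) * (1 / k + 1 / (m - k)))
            elif abs(d) < 1e-12:
                t = 0.0
            else:
                t = np.inf
            if t > best[2]:
                best = (i, j, t)
    return best


def brute_force_fdr_scan(ordered_labels, scores, fdr):
    """Prefix-by-prefix oracle for the control-precision FDR procedure.

    ``ordered_labels``: booleans (True = positive control) for the controls
    in rank order; ``scores``: their logFCs in the same order.  Returns
    (k_star, f_star).
    """
    k_star, f_star = 0, float("-inf")
    n_e = 0
    for k, is_e in enumerate(ordered_labels, start=1):
        n_e += bool(is_e)
        ppv = n_e / k
        if 1 - ppv <= fdr + 1e-12:
            k_star, f_star = k, scores[k - 1]
    return k_star, f_star
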