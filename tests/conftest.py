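import numpy as np
import pytest

from transaug.datasets_io import SimConfig, simulate_transcriptome


@pytest.fixture(scope="session")
def toy_dataset():
    """Small simulated dataset with 3 tissues and both cancer classes."""
    return simulate_transcriptome(
        SimConfig(
            n_samples=240,
            n_genes=30,
            n_tissues=3,
            block_size=6,
            block_rho=0.5,
            cancer_fraction=0.5,
            cancer_shift=0.25,
            noise_sd=0.08,
            seed=7,
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def two_mode_mixture(n: int, seed: int) -> np.ndarray:
    """2-D, 2-component Gaussian mixture inside the unit square."""
    rng = np.random.default_rng(seed)
    comp = rng.integers(0, 2, size=n)
    means = np.array([[0.25, 0.25], [0.75, 0.75]])
    return np.clip(means[comp] + rng.normal(0.0, 0.05, size=(n, 2)), 0.0, 1.0)


# ----------------------------------------------------------------------
# brute-force oracles (independent of the package implementations)
# ----------------------------------------------------------------------


def oracle_precision_recall(true_x, gen_x, k):
    """All-pairs enumeration of the k-NN-ball precision/recall."""

    def radii(pts):
        out = []
        for i, p in enumerate(pts):
            dists = sorted(
                float(np.linalg.norm(p - q)) for j, q in enumerate(pts) if j != i
            )
            out.append(dists[k - 1])
        return out

    r_true = radii(true_x)
    r_gen = radii(gen_x)
    prec_hits = sum(
        1
        for g in gen_x
        if any(np.linalg.norm(g - t) <= r for t, r in zip(true_x, r_true))
    )
    rec_hits = sum(
        1
        for t in true_x
        if any(np.linalg.norm(t - g) <= r for g, r in zip(gen_x, r_gen))
    )
    precision = prec_hits / len(gen_x)
    recall = rec_hits / len(true_x)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def oracle_adversarial_accuracy(true_x, gen_x):
    """Brute-force 1-NN adversarial accuracy (strict inequality)."""

    def nn(p, pts, skip=None):
        return min(
            float(np.linalg.norm(p - q)) for j, q in enumerate(pts) if j != skip
        )

    t_term = np.mean(
        [1.0 if nn(t, gen_x) > nn(t, true_x, skip=i) else 0.0 for i, t in enumerate(true_x)]
    )
    g_term = np.mean(
        [1.0 if nn(g, true_x) > nn(g, gen_x, skip=j) else 0.0 for j, g in enumerate(gen_x)]
    )
    return 0.5 * (t_term + g_term)
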