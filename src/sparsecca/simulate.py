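"""Synthetic paired feature tables with a planted sparse cross-block mode.

The generator emulates the statistical structure sparse CCA assumes in a
two-group brain-behavior study: a behavioral-health block and an imaging
block measured on the same subjects, linked by one shared latent factor that
loads on a small set of variables per block, with correlated nuisance
structure within each block (as morphometric and connectivity features are),
and a second group-specific latent whose variable alignment differs between
groups — producing group-divergent loading profiles like those seen between
younger and older adults.

Generative model per subject i with latent z_i, second latent z2_i, and
group sign g_i (+1 / -1):

    X_i = s * z_i * u' + d * g_i * z2_i * a' + b * F_i * Lx + e,  e ~ N(0, sd^2)

and likewise for Y, where u (a) are sparse unit vectors, F_i are shared
within-block factor scores, and s = ``latent_strength``, d =
``group_divergence``, b = ``within_block_corr``.  The truth record stores
every latent and weight vector so recovery, loading contrasts and
signal-monotonicity can be checked exactly.

Default table shapes follow the study design this emulates: 27 + 26 subjects,
59 behavioral variables, 86 structural (or 249 functional) imaging variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import FeatureTable

__all__ = ["SyntheticSpec", "TruthRecord", "generate_paired_data",
           "generate_null_data"]


@dataclass
class SyntheticSpec:
    """Parameters of the paired-table generator.

    ``latent_strength`` is the amplitude of the shared mode (per-subject sd
    of its contribution along the planted weight vectors); with the default
    noise_sd = 1 the population correlation of the true variate pair is
    s^2 / (s^2 + noise_sd^2), i.e. 0.9 at the default s = 3 — a strong,
    clearly detectable mode.  ``within_block_corr`` scales three shared
    nuisance factors per block; ``group_divergence`` scales the
    group-specific latent.
    """

    n_group_a: int = 27
    n_group_b: int = 26
    p: int = 59
    q: int = 86
    k_x: int = 5
    k_y: int = 5
    latent_strength: float = 3.0
    within_block_corr: float = 0.3
    group_divergence: float = 1.0
    noise_sd: float = 1.0
    n_nuisance_factors: int = 3
    group_names: tuple[str, str] = ("younger", "older")
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_group_a, self.n_group_b, self.p, self.q) <= 0:
            raise ValueError("all dimensions must be positive")
        if not (0 < self.k_x <= self.p and 0 < self.k_y <= self.q):
            raise ValueError("support sizes must satisfy 0 < k <= dim")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.within_block_corr < 1:
            raise ValueError("within_block_corr must be in [0, 1)")
        if self.latent_strength < 0 or self.group_divergence < 0:
            raise ValueError("signal amplitudes must be non-negative")

    @property
    def n(self) -> int:
        return self.n_group_a + self.n_group_b


@dataclass
class TruthRecord:
    """Ground truth behind one generated pair of tables."""

    z: np.ndarray
    z2: np.ndarray
    wx: np.ndarray
    wy: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    group_labels: np.ndarray
    group_sign: np.ndarray
    spec: SyntheticSpec = field(repr=False, default=None)

    @property
    def support_x(self) -> np.ndarray:
        return np.flatnonzero(self.wx)

    @property
    def support_y(self) -> np.ndarray:
        return np.flatnonzero(self.wy)


def _sparse_unit(rng: np.random.Generator, dim: int, k: int,
                 exclude: np.ndarray | None = None) -> np.ndarray:
    """Random unit vector with k nonzeros, support avoiding ``exclude``."""
    pool = np.arange(dim)
    if exclude is not None and dim - exclude.size >= k:
        pool = np.setdiff1d(pool, exclude)
    support = rng.choice(pool, size=k, replace=False)
    w = np.zeros(dim)
    vals = rng.standard_normal(k)
    # keep entries away from zero so the planted support is unambiguous
    vals = np.sign(vals) * (0.5 + np.abs(vals))
    w[support] = vals / np.linalg.norm(vals)
    return w


def generate_paired_data(spec: SyntheticSpec
                         ) -> tuple[FeatureTable, FeatureTable, TruthRecord]:
    """Draw one paired behavioral/imaging dataset from the planted model.

    All randomness flows from ``spec.seed`` through named substreams spawned
    from a single SeedSequence, so the draw for one component never depends
    on the sizes of the others and identical specs give bit-identical tables.
    """
    names = ["latent", "latent2", "weights_x", "weights_y", "div_x", "div_y",
             "factors_x", "factors_y", "loadings_x", "loadings_y",
             "noise_x", "noise_y"]
    children = np.random.SeedSequence(spec.seed).spawn(len(names))
    rng = {nm: np.random.default_rng(ss) for nm, ss in zip(names, children)}

    n = spec.n
    z = rng["latent"].standard_normal(n)
    z2 = rng["latent2"].standard_normal(n)
    g_sign = np.concatenate([np.ones(spec.n_group_a),
                             -np.ones(spec.n_group_b)])
    groups = np.array([spec.group_names[0]] * spec.n_group_a
                      + [spec.group_names[1]] * spec.n_group_b, dtype=object)

    wx = _sparse_unit(rng["weights_x"], spec.p, spec.k_x)
    wy = _sparse_unit(rng["weights_y"], spec.q, spec.k_y)
    ax = _sparse_unit(rng["div_x"], spec.p, spec.k_x, exclude=np.flatnonzero(wx))
    ay = _sparse_unit(rng["div_y"], spec.q, spec.k_y, exclude=np.flatnonzero(wy))

    m = spec.n_nuisance_factors
    # factor scores are drawn independently per block: nuisance correlation
    # is within-block structure and must not couple the two blocks
    Fx = rng["factors_x"].standard_normal((n, m))
    Fy = rng["factors_y"].standard_normal((n, m))
    Lx = rng["loadings_x"].standard_normal((m, spec.p)) / np.sqrt(m)
    Ly = rng["loadings_y"].standard_normal((m, spec.q)) / np.sqrt(m)

    s, d, b = spec.latent_strength, spec.group_divergence, spec.within_block_corr
    # group-divergent score: sign-flipped between groups and partially aligned
    # with the shared latent, so the divergent variables' first-mode loadings
    # have opposite signs in the two groups (a purely independent second
    # latent would be orthogonal to the mode's variate and leave the
    # subgroup loading profiles identical in expectation)
    u_div = g_sign * (z + z2) / np.sqrt(2.0)
    X = (s * np.outer(z, wx)
         + d * np.outer(u_div, ax)
         + b * Fx @ Lx
         + spec.noise_sd * rng["noise_x"].standard_normal((n, spec.p)))
    Y = (s * np.outer(z, wy)
         + d * np.outer(u_div, ay)
         + b * Fy @ Ly
         + spec.noise_sd * rng["noise_y"].standard_normal((n, spec.q)))

    ids = [f"s{i + 1:03d}" for i in range(n)]
    tx = FeatureTable(ids, [f"beh_{j + 1:03d}" for j in range(spec.p)], X,
                      block_label="behavioral", group_labels=groups.copy())
    ty = FeatureTable(ids, [f"img_{j + 1:03d}" for j in range(spec.q)], Y,
                      block_label="imaging", group_labels=groups.copy())
    truth = TruthRecord(z=z, z2=z2, wx=wx, wy=wy, ax=ax, ay=ay,
                        group_labels=groups, group_sign=g_sign, spec=spec)
    return tx, ty, truth


def generate_null_data(n: int, p: int, q: int, seed: int = 0,
                       group_names: tuple[str, str] = ("younger", "older")
                       ) -> tuple[FeatureTable, FeatureTable]:
    """Two independent standard-Gaussian tables with matched subject IDs.

    The blocks share nothing — the calibration input for permutation tests.
    Group labels split the sample as evenly as possible.
    """
    if min(n, p, q) <= 0:
        raise ValueError("dimensions must be positive")
    ss = np.random.SeedSequence(seed).spawn(2)
    X = np.random.default_rng(ss[0]).standard_normal((n, p))
    Y = np.random.default_rng(ss[1]).standard_normal((n, q))
    ids = [f"s{i + 1:03d}" for i in range(n)]
    groups = np.array([group_names[0]] * ((n + 1) // 2)
                      + [group_names[1]] * (n // 2), dtype=object)
    tx = FeatureTable(ids, [f"beh_{j + 1:03d}" for j in range(p)], X,
                      block_label="behavioral", group_labels=groups.copy())
    ty = FeatureTable(ids, [f"img_{j + 1:03d}" for j in range(q)], Y,
                      block_label="imaging", group_labels=groups.copy())
    return tx, ty
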