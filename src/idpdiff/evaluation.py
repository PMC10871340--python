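"""Ensemble-comparison metric suite.

Scores for comparing a generated conformational ensemble against a
reference one, all computed on internal-coordinate features so that every
score is invariant under per-frame rigid motions:

* ``MSE_c`` — mean squared difference of contact-map frequencies (8 Å
  threshold);
* ``MSE_d`` — mean squared difference of ensemble-average Cα-Cα distances,
  reported in nm²;
* ``aKLD_d`` / ``aJSD_d`` — Kullback-Leibler / Jensen-Shannon divergences
  between per-pair Cα-Cα distance histograms, averaged over pairs;
* ``aKLD_t`` / ``aJSD_t`` — the same for per-index α-torsion histograms;
* ``KLD_r`` — divergence between radius-of-gyration histograms;

plus a PCA landscape (components fitted on the reference ensemble's full
distance features, both ensembles projected) and an α-angle helicity
summary.  Divergences are estimated on ε-regularized histograms; KLD is
oriented reference‖generated.  By default, distance-based scores include
pairs with |i−j| ≥ 2 — nearest-neighbour distances are pinned near the
virtual bond length and would dilute the scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .geometry import (
    Ensemble,
    batch_alpha_torsions,
    batch_pairwise_distances,
    contact_frequencies,
    ensemble_rg,
    pair_separations,
)

__all__ = [
    "HistogramSpec",
    "EvaluationReport",
    "mse_c",
    "mse_d",
    "discrete_kld",
    "discrete_jsd",
    "akld_d",
    "akld_t",
    "ajsd_d",
    "ajsd_t",
    "kld_r",
    "pca_landscape",
    "helicity_fraction",
    "count_modes",
    "evaluate",
]


@dataclass(frozen=True)
class HistogramSpec:
    """Binning policy for divergence estimation.

    Distances use ``distance_bins`` over [0, max over both ensembles] per
    feature; torsions use ``torsion_bins`` over (−180°, 180°]; R_g uses
    ``rg_bins`` over the pooled range.  ``eps`` is the pseudo-count added
    to every bin before normalization.
    """

    distance_bins: int = 40
    torsion_bins: int = 36
    rg_bins: int = 40
    eps: float = 1e-6
    min_separation: int = 2
    helical_window: tuple[float, float] = (50.0, 60.0)

    def __post_init__(self) -> None:
        if min(self.distance_bins, self.torsion_bins, self.rg_bins) < 2:
            raise ValueError("bin counts must be >= 2")
        if self.eps <= 0:
            raise ValueError("eps must be > 0")


@dataclass
class EvaluationReport:
    """The seven comparison scores plus bookkeeping metadata."""

    mse_c: float
    mse_d: float
    akld_d: float
    akld_t: float
    ajsd_d: float
    ajsd_t: float
    kld_r: float
    n_ref: int
    n_gen: int
    length: int
    spec: HistogramSpec = field(default_factory=HistogramSpec)
    subsample_seed: int | None = None

    def to_dict(self) -> dict[str, float]:
        return {
            "mse_c": self.mse_c,
            "mse_d": self.mse_d,
            "akld_d": self.akld_d,
            "akld_t": self.akld_t,
            "ajsd_d": self.ajsd_d,
            "ajsd_t": self.ajsd_t,
            "kld_r": self.kld_r,
        }


def _check_lengths(ref: Ensemble, gen: Ensemble) -> int:
    if ref.length != gen.length:
        raise ValueError(
            f"ensembles have different chain lengths: {ref.length} vs {gen.length}"
        )
    return ref.length


def _pair_mask(length: int, min_separation: int) -> np.ndarray:
    return pair_separations(length) >= min_separation


# ---------------------------------------------------------------------------
# contact / distance MSE scores
# ---------------------------------------------------------------------------


def mse_c(
    ref: Ensemble,
    gen: Ensemble,
    threshold: float = 8.0,
    min_separation: int = 2,
) -> float:
    """Mean squared difference of contact frequencies over included pairs."""
    L = _check_lengths(ref, gen)
    f_ref = contact_frequencies(ref, threshold)
    f_gen = contact_frequencies(gen, threshold)
    iu, ju = np.triu_indices(L, k=1)
    mask = (ju - iu) >= min_separation
    return float(np.mean((f_ref[iu, ju][mask] - f_gen[iu, ju][mask]) ** 2))


def mse_d(ref: Ensemble, gen: Ensemble, min_separation: int = 2) -> float:
    """Mean squared difference of mean Cα-Cα distances, in nm²."""
    L = _check_lengths(ref, gen)
    mask = _pair_mask(L, min_separation)
    d_ref = batch_pairwise_distances(ref.coords).mean(axis=0)[mask]
    d_gen = batch_pairwise_distances(gen.coords).mean(axis=0)[mask]
    return float(np.mean((d_ref - d_gen) ** 2) * 0.01)  # Å² → nm²


# ---------------------------------------------------------------------------
# histogram divergences
# ---------------------------------------------------------------------------


def _regularize(counts: np.ndarray, eps: float) -> np.ndarray:
    p = counts.astype(np.float64) + eps
    return p / p.sum()


def discrete_kld(p_counts: np.ndarray, q_counts: np.ndarray, eps: float = 1e-6) -> float:
    """KLD(P‖Q) between two same-binned histograms after ε regularization."""
    p_counts, q_counts = np.asarray(p_counts), np.asarray(q_counts)
    if p_counts.shape != q_counts.shape:
        raise ValueError("histograms must share their binning")
    p = _regularize(p_counts, eps)
    q = _regularize(q_counts, eps)
    return float(np.sum(p * np.log(p / q)))


def discrete_jsd(p_counts: np.ndarray, q_counts: np.ndarray, eps: float = 1e-6) -> float:
    """Jensen-Shannon divergence (symmetric, ≤ ln 2) of two histograms."""
    p_counts, q_counts = np.asarray(p_counts), np.asarray(q_counts)
    if p_counts.shape != q_counts.shape:
        raise ValueError("histograms must share their binning")
    p = _regularize(p_counts, eps)
    q = _regularize(q_counts, eps)
    m = 0.5 * (p + q)
    return float(
        0.5 * np.sum(p * np.log(p / m)) + 0.5 * np.sum(q * np.log(q / m))
    )


def _feature_divergence(
    ref_vals: np.ndarray,
    gen_vals: np.ndarray,
    bins: int,
    ranges: tuple[np.ndarray, np.ndarray] | tuple[float, float],
    eps: float,
    symmetric: bool,
) -> float:
    """Mean per-column histogram divergence of two (N, F) feature arrays."""
    n_feat = ref_vals.shape[1]
    lo, hi = ranges
    lo = np.broadcast_to(np.asarray(lo, dtype=np.float64), (n_feat,))
    hi = np.broadcast_to(np.asarray(hi, dtype=np.float64), (n_feat,))
    total = 0.0
    for j in range(n_feat):
        p, edges = np.histogram(ref_vals[:, j], bins=bins, range=(lo[j], hi[j]))
        q, _ = np.histogram(gen_vals[:, j], bins=bins, range=(lo[j], hi[j]))
        total += discrete_jsd(p, q, eps) if symmetric else discrete_kld(p, q, eps)
    return total / n_feat


def _distance_features(
    ref: Ensemble, gen: Ensemble, spec: HistogramSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    L = _check_lengths(ref, gen)
    mask = _pair_mask(L, spec.min_separation)
    d_ref = batch_pairwise_distances(ref.coords)[:, mask]
    d_gen = batch_pairwise_distances(gen.coords)[:, mask]
    hi = np.maximum(d_ref.max(axis=0), d_gen.max(axis=0))
    return d_ref, d_gen, hi


def akld_d(ref: Ensemble, gen: Ensemble, spec: HistogramSpec = HistogramSpec()) -> float:
    """Mean KLD(ref‖gen) over per-pair Cα-Cα distance histograms."""
    d_ref, d_gen, hi = _distance_features(ref, gen, spec)
    return _feature_divergence(
        d_ref, d_gen, spec.distance_bins, (0.0, hi), spec.eps, symmetric=False
    )


def ajsd_d(ref: Ensemble, gen: Ensemble, spec: HistogramSpec = HistogramSpec()) -> float:
    """Mean JSD over per-pair Cα-Cα distance histograms."""
    d_ref, d_gen, hi = _distance_features(ref, gen, spec)
    return _feature_divergence(
        d_ref, d_gen, spec.distance_bins, (0.0, hi), spec.eps, symmetric=True
    )


def _torsion_features(ref: Ensemble, gen: Ensemble) -> tuple[np.ndarray, np.ndarray]:
    _check_lengths(ref, gen)
    if ref.length < 4:
        raise ValueError("torsion scores require L >= 4")
    return (
        batch_alpha_torsions(ref.coords)[0],
        batch_alpha_torsions(gen.coords)[0],
    )


def akld_t(ref: Ensemble, gen: Ensemble, spec: HistogramSpec = HistogramSpec()) -> float:
    """Mean KLD(ref‖gen) over per-index α-torsion histograms."""
    t_ref, t_gen = _torsion_features(ref, gen)
    return _feature_divergence(
        t_ref, t_gen, spec.torsion_bins, (-180.0, 180.0), spec.eps, symmetric=False
    )


def ajsd_t(ref: Ensemble, gen: Ensemble, spec: HistogramSpec = HistogramSpec()) -> float:
    """Mean JSD over per-index α-torsion histograms."""
    t_ref, t_gen = _torsion_features(ref, gen)
    return _feature_divergence(
        t_ref, t_gen, spec.torsion_bins, (-180.0, 180.0), spec.eps, symmetric=True
    )


def kld_r(ref: Ensemble, gen: Ensemble, spec: HistogramSpec = HistogramSpec()) -> float:
    """KLD(ref‖gen) between radius-of-gyration histograms (pooled range)."""
    _check_lengths(ref, gen)
    rg_ref = ensemble_rg(ref)
    rg_gen = ensemble_rg(gen)
    if min(rg_ref.size, rg_gen.size) < 100:
        import warnings

        warnings.warn("fewer than 100 conformations; KLD_r will be noisy",
                      stacklevel=2)
    lo = min(rg_ref.min(), rg_gen.min())
    hi = max(rg_ref.max(), rg_gen.max())
    p, _ = np.histogram(rg_ref, bins=spec.rg_bins, range=(lo, hi))
    q, _ = np.histogram(rg_gen, bins=spec.rg_bins, range=(lo, hi))
    return discrete_kld(p, q, spec.eps)


# ---------------------------------------------------------------------------
# PCA landscape, helicity, mode counting
# ---------------------------------------------------------------------------


def pca_landscape(
    ref: Ensemble, gen: Ensemble, n_components: int = 2
) -> dict[str, np.ndarray]:
    """PCA on the reference's full Cα-Cα distance features; project both.

    Components are fitted on the reference ensemble only (all i<j pairs)
    and the generated ensemble is projected onto them.  Component signs are
    fixed by making each component's largest-magnitude loading positive.
    """
    _check_lengths(ref, gen)
    if ref.n_conformations < 3:
        raise ValueError("PCA needs at least 3 reference conformations")
    x_ref = batch_pairwise_distances(ref.coords)
    x_gen = batch_pairwise_distances(gen.coords)
    pca = PCA(n_components=n_components, svd_solver="full")
    proj_ref = pca.fit_transform(x_ref)
    flip = np.sign(
        pca.components_[np.arange(n_components),
                        np.argmax(np.abs(pca.components_), axis=1)]
    )
    pca.components_ *= flip[:, None]
    proj_ref *= flip
    proj_gen = pca.transform(x_gen)
    return {
        "ref_projection": proj_ref,
        "gen_projection": proj_gen,
        "components": pca.components_,
        "explained_variance": pca.explained_variance_,
        "mean": pca.mean_,
    }


def helicity_fraction(
    ens: Ensemble, window: tuple[float, float] = (50.0, 60.0)
) -> tuple[float, np.ndarray]:
    """Fraction of α torsions inside the helical window.

    Returns the ensemble mean and the per-torsion profile.  Torsions of
    50–60° correspond to right-handed helical backbone geometry; the
    window width is exposed because helicity definitions vary.
    """
    if ens.length < 4:
        raise ValueError("helicity requires L >= 4")
    angles, _ = batch_alpha_torsions(ens.coords)
    inside = (angles >= window[0]) & (angles <= window[1])
    return float(inside.mean()), inside.mean(axis=0)


def count_modes(
    values: np.ndarray,
    bins: int = 40,
    smooth: int = 3,
    min_prominence_frac: float = 0.05,
) -> int:
    """Number of local maxima in a smoothed histogram of ``values``.

    Used to check bimodality of R_g distributions: the histogram is
    box-smoothed and peaks below ``min_prominence_frac`` of the highest
    peak are ignored.
    """
    counts, _ = np.histogram(values, bins=bins)
    kernel = np.ones(smooth) / smooth
    sm = np.convolve(counts.astype(float), kernel, mode="same")
    from scipy.signal import find_peaks

    peaks, _ = find_peaks(sm, prominence=min_prominence_frac * sm.max())
    # an endpoint can hide a mode from find_peaks; count a dominant edge bin
    for edge in (0, len(sm) - 1):
        neighbour = sm[1] if edge == 0 else sm[-2]
        if sm[edge] > neighbour and sm[edge] >= min_prominence_frac * sm.max():
            peaks = np.append(peaks, edge)
    return int(len(peaks))


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------


def evaluate(
    ref: Ensemble,
    gen: Ensemble,
    spec: HistogramSpec = HistogramSpec(),
    seed: int = 0,
) -> EvaluationReport:
    """All seven scores; ensemble sizes are equalized by seeded subsampling."""
    _check_lengths(ref, gen)
    n = min(ref.n_conformations, gen.n_conformations)
    subsample_seed = None
    if ref.n_conformations != gen.n_conformations:
        subsample_seed = seed
        rng = np.random.default_rng(seed)
        if ref.n_conformations > n:
            idx = rng.choice(ref.n_conformations, size=n, replace=False)
            ref = Ensemble(sequence=ref.sequence, coords=ref.coords[idx])
        if gen.n_conformations > n:
            idx = rng.choice(gen.n_conformations, size=n, replace=False)
            gen = Ensemble(sequence=gen.sequence, coords=gen.coords[idx])
    return EvaluationReport(
        mse_c=mse_c(ref, gen, min_separation=spec.min_separation),
        mse_d=mse_d(ref, gen, min_separation=spec.min_separation),
        akld_d=akld_d(ref, gen, spec),
        akld_t=akld_t(ref, gen, spec),
        ajsd_d=ajsd_d(ref, gen, spec),
        ajsd_t=ajsd_t(ref, gen, spec),
        kld_r=kld_r(ref, gen, spec),
        n_ref=n,
        n_gen=n,
        length=ref.length,
        spec=spec,
        subsample_seed=subsample_seed,
    )
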