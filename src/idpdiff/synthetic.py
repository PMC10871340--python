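"""Seeded toy Cα ensembles with known statistical structure.

Real training data for ensemble generators comes from implicit-solvent
simulations that are far outside a desk-scale budget.  The generators here
stand in for such data in every test and tiny training run: freely-jointed
and self-avoiding coils with a fixed 3.8 Å virtual Cα-Cα bond, ideal
α-helices, and two-state coil/helix mixtures whose radius-of-gyration
distribution is bimodal — the statistical signature of helix-forming
peptides such as the alanine/lysine repeats used as hard cases in the
disordered-ensemble literature.

Every generator is a pure function of its spec (including the seed), so
outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import CANONICAL_AA, Conformation, Ensemble

__all__ = [
    "ToyEnsembleSpec",
    "SamplingFailureError",
    "sample_chain",
    "build_ideal_helix",
    "sample_two_state",
    "perturb_with_noise",
    "assign_toy_sequence",
    "sample_ensemble",
]


class SamplingFailureError(RuntimeError):
    """Raised when self-avoiding sampling exhausts its retry budget."""


@dataclass(frozen=True)
class ToyEnsembleSpec:
    """Specification of a toy ensemble.

    ``model`` is one of ``ideal_chain``, ``self_avoiding_chain``,
    ``ideal_helix`` or ``two_state``.  ``jitter_sigma`` is a per-coordinate
    Gaussian jitter (Å) applied after construction, which gives otherwise
    rigid internal coordinates (exact bonds, ideal helices) a continuous
    distribution; it defaults to 0 so the chain generators keep their exact
    bond length.
    """

    model: str = "ideal_chain"
    length: int = 20
    count: int = 1000
    bond_length: float = 3.8
    clash_distance: float = 4.0
    helix_rise: float = 1.5
    helix_radius: float = 2.3
    helix_twist: float = 100.0
    p_helix: float = 0.5
    jitter_sigma: float = 0.0
    seed: int = 0
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.model not in {
            "ideal_chain",
            "self_avoiding_chain",
            "ideal_helix",
            "two_state",
        }:
            raise ValueError(f"unknown model {self.model!r}")
        if not 0.0 <= self.p_helix <= 1.0:
            raise ValueError("p_helix must be in [0, 1]")
        if self.bond_length <= 0:
            raise ValueError("bond_length must be positive")
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if self.jitter_sigma < 0:
            raise ValueError("jitter_sigma must be >= 0")

    def resolved_sequence(self) -> str:
        if self.sequence is not None:
            return self.sequence
        return assign_toy_sequence(self.length, mode="alternating")


def assign_toy_sequence(L: int, mode: str = "alternating", seed: int = 0) -> str:
    """A toy amino-acid sequence: repeated "AK" pattern or seeded random."""
    if L < 1:
        raise ValueError("L must be >= 1")
    if mode == "alternating":
        return ("AK" * ((L + 1) // 2))[:L]
    if mode == "random":
        rng = np.random.default_rng(seed)
        return "".join(rng.choice(list(CANONICAL_AA), size=L))
    raise ValueError(f"unknown sequence mode {mode!r}")


def _random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _sample_coil(
    spec: ToyEnsembleSpec, rng: np.random.Generator, count: int
) -> np.ndarray:
    """Freely-jointed (and optionally self-avoiding) chains, one rejection
    loop per step with a global retry budget of 100 × count."""
    L, b = spec.length, spec.bond_length
    avoid = spec.model == "self_avoiding_chain"
    budget = 100 * count
    retries = 0
    steps_accepted = 0
    out = np.zeros((count, L, 3))
    for f in range(count):
        chain = np.zeros((L, 3))
        i = 1
        while i < L:
            step = b * _random_unit_vectors(rng, 1)[0]
            cand = chain[i - 1] + step
            if avoid and i >= 2:
                d = np.linalg.norm(chain[: i - 1] - cand, axis=1)
                if np.any(d < spec.clash_distance):
                    retries += 1
                    if retries > budget:
                        acc = steps_accepted / max(steps_accepted + retries, 1)
                        raise SamplingFailureError(
                            f"self-avoiding retry budget {budget} exhausted "
                            f"(acceptance rate {acc:.3f}); reduce length or "
                            f"clash_distance"
                        )
                    continue
            chain[i] = cand
            steps_accepted += 1
            i += 1
        out[f] = chain
    return out


def build_ideal_helix(
    L: int,
    rise: float = 1.5,
    radius: float = 2.3,
    twist: float = 100.0,
) -> Conformation:
    """An ideal right-handed circular helix of Cα atoms.

    Default parameters (1.5 Å rise, 2.3 Å radius, 100°/residue twist) give
    a consecutive Cα chord length of ≈3.8 Å and a constant α torsion of
    ≈+52°, i.e. canonical α-helical backbone geometry.
    """
    if L < 4:
        raise ValueError("need L >= 4 for a helix with defined torsions")
    i = np.arange(L)
    omega = np.radians(twist) * i
    coords = np.stack(
        [radius * np.cos(omega), radius * np.sin(omega), rise * i], axis=1
    )
    return Conformation(coords)


def helix_chord_length(rise: float, radius: float, twist: float) -> float:
    """Closed-form consecutive-Cα distance of a circular helix."""
    return float(
        np.sqrt((2.0 * radius * np.sin(np.radians(twist) / 2.0)) ** 2 + rise**2)
    )


def _jitter(
    coords: np.ndarray, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    if sigma <= 0:
        return coords
    return coords + sigma * rng.standard_normal(coords.shape)


def sample_chain(spec: ToyEnsembleSpec) -> Ensemble:
    """Sample an ensemble of coil chains (ideal or self-avoiding)."""
    if spec.model not in {"ideal_chain", "self_avoiding_chain"}:
        raise ValueError("sample_chain requires a chain model")
    rng = np.random.default_rng(spec.seed)
    coords = _sample_coil(spec, rng, spec.count)
    coords = _jitter(coords, spec.jitter_sigma, rng)
    return Ensemble(sequence=spec.resolved_sequence(), coords=coords)


def sample_two_state(spec: ToyEnsembleSpec) -> Ensemble:
    """Coil/helix mixture: each frame is helical with probability p_helix.

    Helical frames are jittered copies of the ideal helix (random rigid
    orientation); coil frames are freely-jointed chains.  The ground-truth
    state label of each frame (1 = helix) is kept on ``Ensemble.labels``
    for recovery tests but is never an input to any model.
    """
    rng = np.random.default_rng(spec.seed)
    labels = (rng.random(spec.count) < spec.p_helix).astype(np.int8)
    helix = build_ideal_helix(
        spec.length, spec.helix_rise, spec.helix_radius, spec.helix_twist
    ).coords
    helix = helix - helix.mean(axis=0)
    coords = np.zeros((spec.count, spec.length, 3))
    coil_spec = replace(spec, model="ideal_chain")
    for f in range(spec.count):
        if labels[f]:
            coords[f] = helix
        else:
            coords[f] = _sample_coil(coil_spec, rng, 1)[0]
    coords = _jitter(coords, spec.jitter_sigma, rng)
    return Ensemble(
        sequence=spec.resolved_sequence(), coords=coords, labels=labels
    )


def sample_ensemble(spec: ToyEnsembleSpec) -> Ensemble:
    """Dispatch on ``spec.model``; the single entry point used by the CLI."""
    if spec.model in {"ideal_chain", "self_avoiding_chain"}:
        return sample_chain(spec)
    if spec.model == "two_state":
        return sample_two_state(spec)
    rng = np.random.default_rng(spec.seed)
    helix = build_ideal_helix(
        spec.length, spec.helix_rise, spec.helix_radius, spec.helix_twist
    ).coords
    coords = np.repeat(helix[None], spec.count, axis=0)
    coords = _jitter(coords, spec.jitter_sigma, rng)
    return Ensemble(sequence=spec.resolved_sequence(), coords=coords)


def perturb_with_noise(ens: Ensemble, sigma: float, seed: int = 0) -> Ensemble:
    """Add isotropic Gaussian noise of standard deviation ``sigma`` (Å).

    This is both the data-augmentation transform used during autoencoder
    training and the reference perturbation of the reconstruction noise
    control.  ``sigma=0`` returns the coordinates unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return Ensemble(
            sequence=ens.sequence, coords=ens.coords.copy(), labels=ens.labels
        )
    rng = np.random.default_rng(seed)
    noisy = ens.coords + sigma * rng.standard_normal(ens.coords.shape)
    return Ensemble(sequence=ens.sequence, coords=noisy, labels=ens.labels)
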