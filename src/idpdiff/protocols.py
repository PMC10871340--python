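"""Reference toy studies run end-to-end on one CPU.

These functions pin down the package's study conditions — the synthetic
data specs and scaled-down training configurations used to demonstrate
that the latent-diffusion pipeline works — so that tests, the acceptance
script and the command line all execute exactly the same protocol.

The central study mirrors the single-system retraining experiment for a
helix-forming peptide: a two-state (coil/helix) ensemble of an
alanine/lysine-repeat toy peptide with bimodal radius of gyration, on
which an autoencoder and a diffusion model are trained from scratch; a
generated ensemble is then scored against a held-out reference.  Problem
sizes (L = 20, N = 5000 training conformations, 2000-conformation
generated ensembles, small transformer widths) are the package's CPU-scale
defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .autoencoder import (
    AEConfig,
    TrainedAutoencoder,
    batch_reconstruction_report,
    reconstruction_control,
    train_autoencoder,
)
from .diffusion import (
    EncodedSystem,
    NoiseNetConfig,
    TrainedDiffusion,
    build_sigmoid_schedule,
    train_ddpm,
)
from .evaluation import count_modes, evaluate, helicity_fraction
from .geometry import Ensemble, ensemble_rg
from .pipeline import GenerationRequest, ModelBundle, generate_ensemble
from .synthetic import ToyEnsembleSpec, sample_two_state

__all__ = [
    "TWO_STATE_SPEC",
    "AE_STUDY_CONFIG",
    "two_state_datasets",
    "train_study_autoencoder",
    "train_study_ddpm",
    "single_system_study",
    "conditioning_study",
]

# The canonical two-state study condition: an ak-repeat-like 20-mer whose
# ensemble mixes coils and (jittered) ideal helices in equal proportion.
# The 1 Å jitter gives every internal coordinate a continuous distribution
# (a rigid helix would put a point mass in every histogram).
TWO_STATE_SPEC = ToyEnsembleSpec(
    model="two_state",
    length=20,
    count=5000,
    p_helix=0.5,
    jitter_sigma=1.0,
    seed=0,
)

AE_STUDY_CONFIG = AEConfig(
    c=16,
    width=64,
    encoder_blocks=2,
    decoder_blocks=2,
    heads=4,
    epochs=16,
    batch_size=128,
    lr=2e-3,
    seed=0,
)

DDPM_STUDY_NET = NoiseNetConfig(
    c=16, blocks=3, width=64, heads=4, t_emb_dim=32, res_emb_dim=16, seed=0
)

DDPM_STUDY_TRAIN = dict(
    n_frames=4500, epochs=55, batch_size=256, lr=1.2e-3, warmup=100
)


@dataclass
class TwoStateData:
    train: Ensemble
    validation: Ensemble
    reference: Ensemble


def two_state_datasets(seed: int = 0, spec: ToyEnsembleSpec = TWO_STATE_SPEC) -> TwoStateData:
    """Training, validation and held-out reference draws of the study spec."""
    return TwoStateData(
        train=sample_two_state(replace(spec, seed=seed * 3 + 11)),
        validation=sample_two_state(
            replace(spec, count=500, seed=seed * 3 + 12)
        ),
        reference=sample_two_state(
            replace(spec, count=2000, seed=seed * 3 + 13)
        ),
    )


def train_study_autoencoder(
    data: TwoStateData, seed: int = 0, config: AEConfig = AE_STUDY_CONFIG
) -> TrainedAutoencoder:
    return train_autoencoder(
        data.train, data.validation, replace(config, seed=seed)
    )


def train_study_ddpm(
    ae: TrainedAutoencoder,
    systems: list[Ensemble],
    seed: int = 0,
    net: NoiseNetConfig = DDPM_STUDY_NET,
    **overrides,
) -> TrainedDiffusion:
    encoded = [
        EncodedSystem(sequence=e.sequence, encodings=ae.encode_coords(e.coords))
        for e in systems
    ]
    params = {**DDPM_STUDY_TRAIN, **overrides}
    return train_ddpm(
        encoded,
        config=replace(net, seed=seed),
        schedule=build_sigmoid_schedule(),
        seed=seed,
        **params,
    )


def single_system_study(
    seed: int = 0,
    n_generated: int = 2000,
    ae: TrainedAutoencoder | None = None,
    ddpm: TrainedDiffusion | None = None,
    data: TwoStateData | None = None,
) -> dict:
    """The full single-system recovery experiment.

    Trains (or reuses) the autoencoder and diffusion model on the toy
    two-state ensemble, generates an ensemble for the same sequence, and
    returns the comparison scores against the held-out reference together
    with reconstruction/noise-control numbers and the models themselves.
    """
    if data is None:
        data = two_state_datasets(seed)
    if ae is None:
        ae = train_study_autoencoder(data, seed=seed)
    if ddpm is None:
        ddpm = train_study_ddpm(ae, [data.train], seed=seed)
    bundle = ModelBundle(
        ae=ae,
        ddpm=ddpm,
        metadata={
            "seed": seed,
            "trained_lengths": [data.train.length, data.train.length],
        },
    )
    request = GenerationRequest(
        sequence=data.train.sequence, n=n_generated, steps=100, seed=seed + 500
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # geometry-sanity warning is logged
        generated = generate_ensemble(request, bundle)
    report = evaluate(data.reference, generated, seed=seed)

    recon = ae.reconstruct(data.reference.coords)
    rec_report = batch_reconstruction_report(
        data.reference.coords, recon, ae.scaler
    )
    control = reconstruction_control(
        data.reference, [0.01, 0.1], ae.scaler, seed=seed
    )
    return {
        "data": data,
        "ae": ae,
        "ddpm": ddpm,
        "bundle": bundle,
        "generated": generated,
        "report": report,
        "reconstruction": rec_report,
        "noise_control": control,
        "rg_modes_reference": count_modes(ensemble_rg(data.reference)),
        "rg_modes_generated": count_modes(ensemble_rg(generated)),
        "helicity_reference": helicity_fraction(data.reference)[0],
        "helicity_generated": helicity_fraction(generated)[0],
    }


def conditioning_study(
    seed: int = 0,
    ae: TrainedAutoencoder | None = None,
    n_generated: int = 400,
    **train_overrides,
) -> dict:
    """Sequence-conditioning check on two systems of distinct compactness.

    A coil-only system and a helix-dominated system (distinct sequences,
    same length) are encoded with one autoencoder and modelled by a single
    sequence-conditional DDPM; generated ensembles must order correctly by
    mean radius of gyration.
    """
    coil_spec = replace(
        TWO_STATE_SPEC, p_helix=0.0, seed=seed * 5 + 31, sequence="AK" * 10
    )
    helix_spec = replace(
        TWO_STATE_SPEC, p_helix=0.9, seed=seed * 5 + 32, sequence="AE" * 10
    )
    coil = sample_two_state(coil_spec)
    helix = sample_two_state(helix_spec)
    if ae is None:
        data = two_state_datasets(seed)
        ae = train_study_autoencoder(data, seed=seed)
    overrides = {**dict(epochs=35, n_frames=2000, lr=1.5e-3), **train_overrides}
    ddpm = train_study_ddpm(ae, [coil, helix], seed=seed, **overrides)
    bundle = ModelBundle(ae=ae, ddpm=ddpm, metadata={"trained_lengths": [20, 20]})
    out = {}
    import warnings

    for name, ens in (("coil", coil), ("helix", helix)):
        req = GenerationRequest(
            sequence=ens.sequence, n=n_generated, steps=100, seed=seed + 900
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gen = generate_ensemble(req, bundle)
        rg = ensemble_rg(gen)
        out[name] = {
            "reference_rg": ensemble_rg(ens),
            "generated_rg": rg,
        }
    return {"ae": ae, "ddpm": ddpm, "results": out}
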