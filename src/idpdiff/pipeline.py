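"""End-to-end generation pipeline and file I/O.

Glue between the trained models and the outside world: given an amino-acid
sequence, sample encodings from the diffusion model, decode them to Cα
coordinates, and return (or write) the resulting ensemble.  Ensembles are
interchanged as multi-MODEL Cα-only PDB files plus FASTA sequences; model
checkpoints are bundled in a directory with provenance metadata.

The whole path is deterministic given (bundle, request): the same seed
yields byte-identical PDB output.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.sequence import ProteinSequence
from biotite.structure.io.pdb import PDBFile

from .autoencoder import TrainedAutoencoder
from .diffusion import SequenceCondition, TrainedDiffusion
from .geometry import CANONICAL_AA, Ensemble

__all__ = [
    "ModelBundle",
    "GenerationRequest",
    "PDBFormatError",
    "generate_ensemble",
    "read_ensemble_pdb",
    "write_ensemble_pdb",
    "read_fasta",
    "write_fasta",
]

logger = logging.getLogger("idpdiff")

BOND_SANITY_RANGE = (2.8, 4.8)  # Å, plausible consecutive Cα distances


class PDBFormatError(ValueError):
    """Raised for malformed multi-MODEL Cα-trace PDB input."""


@dataclass(frozen=True)
class GenerationRequest:
    """What to generate: sequence, ensemble size, sampling steps, seed."""

    sequence: str
    n: int = 10_000
    steps: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        bad = set(self.sequence) - set(CANONICAL_AA)
        if bad:
            raise ValueError(f"invalid residue letter(s): {sorted(bad)}")
        if len(self.sequence) < 4:
            raise ValueError("sequence must have at least 4 residues")


@dataclass
class ModelBundle:
    """A matched autoencoder + diffusion model pair with provenance.

    ``metadata`` records seeds, training configs and a fingerprint of the
    training data; ``trained_lengths`` is the (min, max) peptide length
    seen in training, used to warn on extrapolation.
    """

    ae: TrainedAutoencoder
    ddpm: TrainedDiffusion
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ae.config.c != self.ddpm.config.c:
            raise ValueError(
                f"encoding width mismatch between checkpoints: "
                f"AE c={self.ae.config.c}, DDPM c={self.ddpm.config.c}"
            )

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.ae.save(directory)
        self.ddpm.save(directory)
        (directory / "bundle.json").write_text(
            json.dumps({"format_version": 1, "metadata": self.metadata}, indent=1)
        )

    @classmethod
    def load(cls, directory: str | Path) -> "ModelBundle":
        directory = Path(directory)
        info = json.loads((directory / "bundle.json").read_text())
        if info.get("format_version") != 1:
            raise ValueError("unrecognized bundle version")
        return cls(
            ae=TrainedAutoencoder.load(directory),
            ddpm=TrainedDiffusion.load(directory),
            metadata=info.get("metadata", {}),
        )


def generate_ensemble(req: GenerationRequest, bundle: ModelBundle) -> Ensemble:
    """Sequence → sampled encodings → decoded Cα ensemble.

    Decoded geometry is sanity-checked: if fewer than 99% of consecutive
    Cα distances fall in the plausible 2.8–4.8 Å band, a warning is issued
    (never a silent pass).
    """
    lengths = bundle.metadata.get("trained_lengths")
    if lengths and not lengths[0] <= len(req.sequence) <= lengths[1]:
        warnings.warn(
            f"sequence length {len(req.sequence)} outside trained range "
            f"{lengths}; generated ensemble may be unreliable",
            stacklevel=2,
        )
    cond = SequenceCondition.from_sequence(req.sequence)
    logger.info("sampling %d encodings (steps=%d, seed=%d)", req.n, req.steps, req.seed)
    z = bundle.ddpm.sample(req.n, cond, steps=req.steps, seed=req.seed)
    logger.info("decoding %d encodings", req.n)
    coords = bundle.ae.decode_encodings(z.astype(np.float32))
    bonds = np.linalg.norm(np.diff(coords, axis=1), axis=2)
    ok = np.mean((bonds >= BOND_SANITY_RANGE[0]) & (bonds <= BOND_SANITY_RANGE[1]))
    logger.info("consecutive-Ca sanity: %.2f%% in %s", 100 * ok, BOND_SANITY_RANGE)
    if ok < 0.99:
        warnings.warn(
            f"only {100 * ok:.1f}% of consecutive Cα distances fall in the "
            f"{BOND_SANITY_RANGE} Å sanity band",
            stacklevel=2,
        )
    return Ensemble(sequence=req.sequence, coords=coords)


# ---------------------------------------------------------------------------
# multi-MODEL Cα-only PDB
# ---------------------------------------------------------------------------

_THREE_TO_ONE = {
    ProteinSequence.convert_letter_1to3(a).upper(): a for a in CANONICAL_AA
}


def write_ensemble_pdb(ens: Ensemble, path: str | Path) -> None:
    """Write an ensemble as a multi-MODEL PDB with one CA atom per residue.

    Residues are numbered 1-based and named by the standard three-letter
    code of the sequence.  Coordinates are written at the PDB fixed
    precision (3 decimals, Å).
    """
    n, length = ens.n_conformations, ens.length
    template = struc.AtomArray(length)
    template.coord = ens.coords[0].astype(np.float32)
    template.chain_id = np.full(length, "A")
    template.res_id = np.arange(1, length + 1)
    template.res_name = np.array(
        [ProteinSequence.convert_letter_1to3(a).upper() for a in ens.sequence]
    )
    template.atom_name = np.full(length, "CA")
    template.element = np.full(length, "C")
    template.hetero = np.zeros(length, dtype=bool)
    stack = struc.stack([template] * n)
    stack.coord = ens.coords.astype(np.float32)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_ensemble_pdb(path: str | Path) -> Ensemble:
    """Read a multi-MODEL Cα-only PDB into an Ensemble (validating heavily)."""
    try:
        pdb = PDBFile.read(str(path))
        count = pdb.get_model_count()
        arrays = [pdb.get_structure(model=m) for m in range(1, count + 1)]
    except Exception as exc:  # biotite raises various parse errors
        raise PDBFormatError(f"cannot parse PDB file {path}: {exc}") from exc
    lengths = {a.array_length() for a in arrays}
    if len(lengths) != 1:
        raise PDBFormatError(
            f"inconsistent residue counts across MODELs in {path}: "
            f"{sorted(a.array_length() for a in arrays)}"
        )
    first = arrays[0]
    for m, arr in enumerate(arrays, start=1):
        not_ca = np.nonzero(arr.atom_name != "CA")[0]
        if not_ca.size:
            i = not_ca[0]
            raise PDBFormatError(
                f"MODEL {m}: atom {arr.atom_name[i]!r} at residue "
                f"{arr.res_id[i]} is not a CA"
            )
        if np.unique(arr.res_id).size != arr.array_length():
            raise PDBFormatError(f"MODEL {m}: duplicate CA for a residue")
        if not np.array_equal(arr.res_id, first.res_id) or not np.array_equal(
            arr.res_name, first.res_name
        ):
            raise PDBFormatError(f"MODEL {m}: residue records differ from MODEL 1")
    sequence = []
    for res_id, res_name in zip(first.res_id, first.res_name):
        one = _THREE_TO_ONE.get(str(res_name).upper())
        if one is None:
            raise PDBFormatError(
                f"unknown residue name {res_name!r} at residue {res_id}"
            )
        sequence.append(one)
    coords = np.stack([a.coord for a in arrays]).astype(np.float64)
    return Ensemble(sequence="".join(sequence), coords=coords)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Header → sequence pairs; lowercase is uppercased, non-canonical
    letters are rejected with their position."""
    from biotite.sequence.io.fasta import FastaFile

    fasta = FastaFile.read(str(path))
    out: dict[str, str] = {}
    for header, seq in fasta.items():
        seq = seq.upper()
        for i, a in enumerate(seq):
            if a not in CANONICAL_AA:
                raise ValueError(
                    f"record {header!r}: invalid residue letter {a!r} at "
                    f"position {i + 1}"
                )
        out[header] = seq
    return out


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    from biotite.sequence.io.fasta import FastaFile

    fasta = FastaFile()
    for header, seq in sequences.items():
        fasta[header] = seq
    fasta.write(str(path))
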