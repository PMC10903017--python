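"""Synthetic inputs with the statistical structure the pipeline assumes.

Two generators cover the pipeline's two data kinds:

* protein families diverged from a common ancestor at controlled identity
  levels (per-site substitutions, geometric-length deletions kept in the
  ancestor coordinate frame, so the family is born aligned);
* noisy piecewise-linear substrate-depletion / product-formation time
  courses of the kind produced by resting-cell bioconversion assays.

:func:`simulate_design_study` additionally assembles a complete synthetic
stand-in for a consensus-design study: a decarboxylase-sized reference, a
high-identity homolog tier and a broader tier with defined key-residue
divergence, so the whole selection → consensus → gene-design → scoring
chain can run end to end without any external sequence data.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment_io import AMINO_ACIDS, GAP, AlignedFamily, GappedSequence, ProteinSequence
from .errors import InputError
from .pathway_quant import (
    DEFAULT_STOICHIOMETRY,
    BioconversionSeries,
    PathwayStoichiometry,
    stoich_convert,
)

_AA = np.frombuffer(AMINO_ACIDS.encode(), dtype="S1").astype("U1")


@dataclass(frozen=True)
class FamilySimConfig:
    """Controls for the ancestor-derived protein-family generator."""

    ancestor_length: int = 500
    n_members: int = 8
    substitution_prob: float = 0.05
    indel_prob: float = 0.0
    indel_mean_len: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ancestor_length <= 0:
            raise InputError("ancestor_length must be positive")
        if self.n_members < 2:
            raise InputError("n_members must be >= 2")
        for name in ("substitution_prob", "indel_prob"):
            p = getattr(self, name)
            if not 0.0 <= p < 1.0:
                raise InputError(f"{name} must be in [0, 1)")
        if self.indel_mean_len < 1.0:
            raise InputError("indel_mean_len must be >= 1")


@dataclass(frozen=True)
class KineticsSimConfig:
    """Controls for the bioconversion time-course generator.

    Defaults emulate a resting-cell assay starting from ~100 mg/L substrate
    consumed at 26 mg/L/h (so depletion plateaus just before 4 h), sampled
    densely in the first two hours and sparsely afterwards.
    """

    true_rate: float = 26.0
    plateau_time: float = 100.0 / 26.0
    sampling_times: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0, 4.0, 6.0, 8.0, 24.0)
    noise_sd: float = 0.0
    seed: int = 0
    substrate: str = "tCA"
    product: str = "styrene"

    def __post_init__(self) -> None:
        if self.true_rate <= 0:
            raise InputError("true_rate must be positive")
        if self.plateau_time <= 0:
            raise InputError("plateau_time must be positive")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be non-negative")
        times = self.sampling_times
        if len(times) < 2 or any(b <= a for a, b in zip(times, times[1:])):
            raise InputError("sampling_times must be >= 2 strictly increasing values")
        if times[0] < 0:
            raise InputError("sampling_times must be non-negative")


def _random_protein(length: int, rng: np.random.Generator, seq_id: str) -> ProteinSequence:
    residues = "".join(_AA[rng.integers(0, len(_AA), size=length)])
    return ProteinSequence(id=seq_id, residues=residues)


def _substitute(
    residues: np.ndarray, prob: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-site substitution, uniform over the 19 alternative residues."""
    out = residues.copy()
    mask = rng.random(len(out)) < prob
    if mask.any():
        idx = np.searchsorted(_AA, out[mask])
        offset = rng.integers(1, len(_AA), size=int(mask.sum()))
        out[mask] = _AA[(idx + offset) % len(_AA)]
    return out


def _delete_sites(
    length: int, indel_prob: float, mean_len: float, rng: np.random.Generator
) -> np.ndarray:
    """Boolean deletion mask: each site may start a geometric-length deletion."""
    deleted = np.zeros(length, dtype=bool)
    i = 0
    while i < length:
        if rng.random() < indel_prob:
            run = int(rng.geometric(1.0 / mean_len))
            deleted[i:i + run] = True
            i += run
        else:
            i += 1
    return deleted


def simulate_family(config: FamilySimConfig) -> tuple[ProteinSequence, AlignedFamily]:
    """Simulate homologs diverged from one ancestor, pre-aligned to it.

    Indels are modelled as deletions relative to the ancestor frame only, so
    every member has the ancestor's length with gaps, and the family is an
    exact alignment by construction.
    """
    rng = np.random.default_rng(config.seed)
    ancestor = _random_protein(config.ancestor_length, rng, "ancestor")
    anc = np.array(list(ancestor.residues), dtype="U1")
    members = []
    for k in range(config.n_members):
        residues = _substitute(anc, config.substitution_prob, rng)
        if config.indel_prob > 0:
            deleted = _delete_sites(
                len(residues), config.indel_prob, config.indel_mean_len, rng
            )
            residues = residues.copy()
            residues[deleted] = GAP
        row = "".join(residues)
        if not row.replace(GAP, ""):
            raise InputError("simulated member lost every residue; lower indel_prob")
        members.append(GappedSequence(id=f"hom{k + 1:02d}", residues=row))
    family = AlignedFamily(
        members=tuple(members), query_id=ancestor.id, source_format="aligned-fasta"
    )
    return ancestor, family


def simulate_bioconversion(
    config: KineticsSimConfig,
    stoich: PathwayStoichiometry = DEFAULT_STOICHIOMETRY,
) -> tuple[BioconversionSeries, BioconversionSeries]:
    """Simulate a substrate-depletion / product-formation pair.

    The substrate declines linearly at ``true_rate`` until ``plateau_time``
    and then holds; the product mirrors the consumed substrate under pathway
    stoichiometry.  Gaussian noise (sd ``noise_sd``) is added independently
    to every sample and concentrations are floored at zero.
    """
    rng = np.random.default_rng(config.seed)
    s0 = config.true_rate * config.plateau_time
    sub, prod = [], []
    for t in config.sampling_times:
        s = s0 - config.true_rate * min(t, config.plateau_time)
        consumed = s0 - s
        p = stoich_convert(consumed, config.substrate, config.product, stoich)
        if config.noise_sd > 0:
            s += rng.normal(0.0, config.noise_sd)
            p += rng.normal(0.0, config.noise_sd)
        sub.append((t, max(s, 0.0)))
        prod.append((t, max(p, 0.0)))
    return (
        BioconversionSeries(analyte=config.substrate, samples=tuple(sub)),
        BioconversionSeries(analyte=config.product, samples=tuple(prod)),
    )


#: Catalytically important positions (1-based) of the decarboxylase
#: reference and their required residues, used by the synthetic study.
STUDY_KEY_RESIDUES: dict[int, str] = {189: "I", 192: "Q", 330: "I", 397: "F", 398: "I"}


@dataclass(frozen=True)
class DesignStudy:
    """A fully synthetic consensus-design study (stand-in data).

    ``reference`` plays the role of the query enzyme; ``candidates`` are the
    degapped homologs (high-identity tier first); ``aligned`` holds every
    homolog in the reference coordinate frame.  ``deleted_column`` is the
    1-based alignment column where most members carry a deletion, and
    ``key_residues``/``divergent_key_residues`` define the conservation
    pattern built into the two tiers.
    """

    reference: ProteinSequence
    candidates: tuple[ProteinSequence, ...]
    aligned: AlignedFamily
    high_tier_ids: tuple[str, ...]
    deleted_column: int
    key_residues: dict[int, str]
    divergent_key_residues: dict[int, str]


def _study_member(
    reference: ProteinSequence,
    anc: np.ndarray,
    identity_band: tuple[float, float],
    rng: np.random.Generator,
    pinned: dict[int, str],
    gapped_cols: tuple[int, ...],
    seq_id: str,
    max_attempts: int = 30,
) -> GappedSequence:
    """One homolog whose measured identity to the reference lies in a band.

    Alignment-based identity runs slightly above 1 - substitution rate (the
    aligner can gap out runs of mismatches), so the substitution rate is
    steered by feedback from the measured identity until it lands in the
    band.  Deterministic for a given rng state.
    """
    from .family_selection import pairwise_identity  # avoid import cycle at module load

    lo, hi = identity_band
    target = float(rng.uniform(lo, hi))
    prob = 1.0 - target
    best: tuple[float, GappedSequence] | None = None
    for _ in range(max_attempts):
        residues = _substitute(anc, prob, rng)
        for pos, res in pinned.items():
            residues[pos - 1] = res
        for col in gapped_cols:
            residues[col - 1] = GAP
        member = GappedSequence(id=seq_id, residues="".join(residues))
        ident = pairwise_identity(reference, member.degap())
        if lo < ident < hi:
            return member
        miss = abs(ident - target)
        if best is None or miss < best[0]:
            best = (miss, member)
        prob = min(0.95, max(0.01, prob + (ident - target)))
    assert best is not None
    return best[1]


def simulate_design_study(
    seed: int = 0,
    reference_length: int = 503,
    n_high: int = 8,
    n_mid: int = 66,
    high_identity_band: tuple[float, float] = (0.65, 0.88),
    mid_identity_band: tuple[float, float] = (0.52, 0.58),
    deleted_column: int = 251,
) -> DesignStudy:
    """Build a synthetic stand-in for an identity-stratified design study.

    The reference is a random 503-residue protein carrying the canonical key
    residues (I189, Q192, I330, F397, I398).  The high-identity tier
    (measured identity inside ``high_identity_band``, i.e. strictly above
    60%) keeps all five conserved, and a plurality of its members share one
    deleted column, so its consensus is one residue shorter than the
    reference.  The broader tier (identity in ``mid_identity_band``, between
    50% and 60%) carries Y397/T398 instead, mirroring the kind of
    active-site divergence that separates a functional consensus design
    from a non-functional one.  Entirely synthetic: no real enzyme sequence
    is used or approximated.
    """
    rng = np.random.default_rng(seed)
    reference = _random_protein(reference_length, rng, "reference")
    anc = np.array(list(reference.residues), dtype="U1")
    for pos, res in STUDY_KEY_RESIDUES.items():
        anc[pos - 1] = res
    reference = ProteinSequence(
        id="reference",
        residues="".join(anc),
        description="synthetic decarboxylase-like query",
    )

    members: list[GappedSequence] = []
    high_ids = []
    for k in range(n_high):
        gap_cols = (deleted_column,) if k < (n_high * 3) // 4 else ()
        m = _study_member(
            reference, anc, high_identity_band, rng,
            dict(STUDY_KEY_RESIDUES), gap_cols, f"high{k + 1:02d}",
        )
        members.append(m)
        high_ids.append(m.id)

    divergent = dict(STUDY_KEY_RESIDUES)
    divergent.update({397: "Y", 398: "T"})
    for k in range(n_mid):
        m = _study_member(
            reference, anc, mid_identity_band, rng,
            divergent, (deleted_column,), f"mid{k + 1:02d}",
        )
        members.append(m)

    aligned = AlignedFamily(
        members=tuple(members), query_id=reference.id, source_format="aligned-fasta"
    )
    candidates = tuple(m.degap() for m in members)
    return DesignStudy(
        reference=reference,
        candidates=candidates,
        aligned=aligned,
        high_tier_ids=tuple(high_ids),
        deleted_column=deleted_column,
        key_residues=dict(STUDY_KEY_RESIDUES),
        divergent_key_residues={397: "Y", 398: "T"},
    )
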