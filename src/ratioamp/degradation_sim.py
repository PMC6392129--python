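"""Mechanistic simulator of RNA degradation read out as RT-qPCR plates.

Damage is modeled as a Poisson process along the template: at an expected
rate of lam events per nucleotide, a region of length L escapes damage
with probability exp(-lam * L).  Two mechanisms are distinguished:

``strand_break``
    Backbone scission (heat, ribonucleases).  Fragments the molecule, so
    it is visible to electrophoretic integrity scores *and* abolishes
    amplification across the region.
``blocking_lesion``
    Covalent damage such as UV-induced intramolecular pyrimidine
    crosslinks.  The strand stays intact — electrophoresis sees nothing —
    but the lesion stops the reverse transcriptase/polymerase just as a
    break does.

Both mechanisms therefore share the survival form for qPCR, and differ
only in electrophoretic visibility.  Template loss maps to a cycle delay
via amplification kinetics: losing a fraction of templates costs
``ln(1/survival)/ln(1 + efficiency)`` cycles.  Gaussian noise (default sd
0.15 cycles, a typical technical-replicate spread) is added per well, and
Cts reaching the assay's cycle cap are censored to not-detected.

An electrophoretic surrogate score, :func:`pseudo_rin`, stands in for the
proprietary microfluidics integrity number.  It is synthetic by
construction: ``1 + 9 * exp(-p * L_23S)`` where ``p`` is the *strand-break*
rate only (blocking lesions leave it at the top of the scale).  It is
contractual only in its monotonicity and its blindness to blocking
lesions, never in numeric agreement with any vendor score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import DataError, DomainError
from .qpcr_io import NOT_DETECTED, AmpliconAssay, CtObservation, Panel

__all__ = [
    "MECHANISMS",
    "TranscriptSpecies",
    "TranscriptPool",
    "DegradationModel",
    "SimulatedPlate",
    "survival_fraction",
    "ct_shift",
    "rate_from_shift",
    "simulate_plate",
    "estimate_rate",
    "pseudo_rin",
    "default_panel",
    "default_pool",
    "demo_models",
]

MECHANISMS = ("strand_break", "blocking_lesion")

RNA_CLASSES = ("mRNA", "rRNA_16S", "rRNA_23S")


@dataclass(frozen=True)
class TranscriptSpecies:
    """One RNA species in the pool and its undamaged Cts per assay."""

    species_id: str
    length: int
    rna_class: str = "mRNA"
    baseline_ct: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise DomainError(f"{self.species_id}: length must be > 0")
        if self.rna_class not in RNA_CLASSES:
            raise DomainError(
                f"{self.species_id}: rna_class must be one of {RNA_CLASSES}"
            )


@dataclass(frozen=True)
class TranscriptPool:
    """The RNA extract: species plus the rRNA share of total mass.

    Ribosomal RNA makes up 80%-85% of a typical total-RNA extract; the
    default mass fraction is the midpoint, 0.825.
    """

    species: tuple[TranscriptSpecies, ...]
    rrna_mass_fraction: float = 0.825

    def __post_init__(self) -> None:
        if not (0.0 <= self.rrna_mass_fraction <= 1.0):
            raise DomainError("rrna_mass_fraction must be in [0, 1]")

    def species_for_assay(self, assay_id: str) -> TranscriptSpecies:
        for sp in self.species:
            if assay_id in sp.baseline_ct:
                return sp
        raise DataError(f"no species in pool carries a baseline for {assay_id!r}")

    def by_class(self, rna_class: str) -> TranscriptSpecies:
        for sp in self.species:
            if sp.rna_class == rna_class:
                return sp
        raise DataError(f"pool has no species of class {rna_class!r}")


@dataclass(frozen=True)
class DegradationModel:
    """Damage mechanism plus per-nucleotide event rate(s).

    ``level_map`` orders the degradation series (label -> lam); rates must
    be non-decreasing along it.  ``rate_per_nt`` may be used instead for a
    single-point model.
    """

    mechanism: str
    rate_per_nt: float | None = None
    level_map: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise DomainError(f"mechanism must be one of {MECHANISMS}")
        if self.rate_per_nt is None and self.level_map is None:
            raise DomainError("provide rate_per_nt or level_map")
        if self.rate_per_nt is not None and self.rate_per_nt < 0:
            raise DomainError("rate_per_nt must be >= 0")
        if self.level_map is not None:
            rates = list(self.level_map.values())
            if any(r < 0 for r in rates):
                raise DomainError("level rates must be >= 0")
            if any(b < a for a, b in zip(rates, rates[1:])):
                raise DomainError("level rates must be non-decreasing in level order")

    @property
    def levels(self) -> tuple[str, ...]:
        if self.level_map is None:
            raise DomainError("model has no level_map")
        return tuple(self.level_map)

    def rate_at(self, level: str | None = None) -> float:
        if level is None:
            if self.rate_per_nt is None:
                raise DomainError("model has no single rate; pass a level")
            return self.rate_per_nt
        if self.level_map is None or level not in self.level_map:
            raise DataError(f"unknown degradation level {level!r}")
        return self.level_map[level]


@dataclass(frozen=True)
class SimulatedPlate:
    """A reproducible synthetic plate: same inputs, identical observations."""

    observations: tuple[CtObservation, ...]
    seed: int
    model: DegradationModel
    noise_sd: float
    scenario: str = ""


def survival_fraction(amplicon_length: float, rate_per_nt: float) -> float:
    """Probability that a region of length L carries zero damage events.

    Poisson damage at rate lam per nucleotide gives ``exp(-lam * L)``;
    identical for strand breaks and blocking lesions, since either kind of
    event abolishes amplification across the region.
    """
    if amplicon_length <= 0:
        raise DomainError("amplicon_length must be > 0")
    if rate_per_nt < 0:
        raise DomainError("rate_per_nt must be >= 0")
    return math.exp(-rate_per_nt * amplicon_length)


def ct_shift(survival: float, efficiency: float) -> float:
    """Cycle delay caused by losing templates, ``ln(1/s)/ln(1+E)``.

    With perfect efficiency (E = 1) this is ``log2(1/s)``: halving the
    template costs one doubling.  ``survival == 0`` returns ``inf`` (the
    assay will censor).
    """
    if not (0.0 <= survival <= 1.0):
        raise DomainError("survival must be in [0, 1]")
    if not (0.0 < efficiency <= 1.0):
        raise DomainError("efficiency must be in (0, 1]")
    if survival == 0.0:
        return math.inf
    return math.log(1.0 / survival) / math.log1p(efficiency)


def rate_from_shift(delta_ct: float, amplicon_length: float, efficiency: float) -> float:
    """Invert :func:`ct_shift` ∘ :func:`survival_fraction` for one assay:
    ``lam = delta_ct * ln(1+E) / L``."""
    if amplicon_length <= 0:
        raise DomainError("amplicon_length must be > 0")
    if not (0.0 < efficiency <= 1.0):
        raise DomainError("efficiency must be in (0, 1]")
    return delta_ct * math.log1p(efficiency) / amplicon_length


def _well_rng(seed: int, level_idx: int, assay_idx: int, replicate: int) -> np.random.Generator:
    # Independent stream per well, deterministic in (seed, level, assay, rep).
    return np.random.default_rng([seed, level_idx, assay_idx, replicate])


def simulate_plate(
    pool: TranscriptPool,
    panel: Panel,
    model: DegradationModel,
    noise_sd: float = 0.15,
    replicates: int = 3,
    seed: int = 0,
    scenario: str = "",
) -> SimulatedPlate:
    """Simulate a full degradation series of Ct plates.

    For every (level, assay, replicate):
    ``Ct = baseline + ct_shift(survival_fraction(L_assay, lam_level), E)
    + N(0, noise_sd)``, censored to NOT_DETECTED at or above the assay's
    cycle cap.  ``sample_id`` is ``<scenario>_<level>``.  Identical inputs
    produce identical plates; each well draws from its own seeded stream.
    """
    if model.level_map is None:
        raise DomainError("simulate_plate requires a model with a level_map")
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    if replicates < 1:
        raise DomainError("replicates must be >= 1")
    label = scenario or model.mechanism
    assays = list(panel.assays.values())
    # Validate targets up front so failures name the assay, not a well.
    for assay in assays:
        pool.species_for_assay(assay.assay_id)
    observations: list[CtObservation] = []
    for level_idx, (level, lam) in enumerate(model.level_map.items()):
        sample_id = f"{label}_{level}"
        for assay_idx, assay in enumerate(assays):
            species = pool.species_for_assay(assay.assay_id)
            baseline = species.baseline_ct[assay.assay_id]
            if baseline >= assay.max_cycles:
                raise DataError(
                    f"baseline Ct {baseline} for {assay.assay_id!r} is not below "
                    f"the {assay.max_cycles}-cycle cap"
                )
            shift = ct_shift(
                survival_fraction(assay.amplicon_length, lam), assay.efficiency
            )
            for rep in range(1, replicates + 1):
                noise = 0.0
                if noise_sd > 0:
                    rng = _well_rng(seed, level_idx, assay_idx, rep)
                    noise = float(rng.normal(0.0, noise_sd))
                ct = baseline + shift + noise
                observations.append(
                    CtObservation(
                        sample_id=sample_id,
                        assay_id=assay.assay_id,
                        replicate=rep,
                        ct=NOT_DETECTED if ct >= assay.max_cycles else ct,
                        melt_pass=True,
                        degradation_level=level,
                    )
                )
    return SimulatedPlate(
        observations=tuple(observations),
        seed=seed,
        model=model,
        noise_sd=noise_sd,
        scenario=label,
    )


def estimate_rate(
    plate: SimulatedPlate,
    pool: TranscriptPool,
    panel: Panel,
    level: str,
) -> float:
    """Recover the per-nucleotide damage rate at one level of a plate.

    Pools every uncensored assay by weighted least squares against the
    known undamaged baselines: with ``x_a = L_a / ln(1+E_a)`` and
    ``dCt_a`` the replicate-mean Ct minus baseline,
    ``lam_hat = sum(x_a * dCt_a) / sum(x_a**2)``.  Noiseless plates give
    the exact rate; noisy plates average the noise across assays and
    replicates.
    """
    num = 0.0
    den = 0.0
    for assay in panel.assays.values():
        species = pool.species_for_assay(assay.assay_id)
        baseline = species.baseline_ct[assay.assay_id]
        cts = [
            float(o.ct)
            for o in plate.observations
            if o.assay_id == assay.assay_id
            and o.degradation_level == level
            and o.melt_pass
            and o.detected
        ]
        if not cts:
            continue  # fully censored assay carries no usable shift
        x = assay.amplicon_length / math.log1p(assay.efficiency)
        num += x * (float(np.mean(cts)) - baseline)
        den += x * x
    if den == 0.0:
        raise DataError(f"no uncensored assay at level {level!r}")
    return num / den


def pseudo_rin(
    model: DegradationModel,
    pool: TranscriptPool,
    level: str | None = None,
) -> float:
    """Electrophoretic-surrogate integrity score on [1, 10] (synthetic).

    Only strand breaks are electrophoretically visible, so the effective
    rate is lam for ``strand_break`` and 0 for ``blocking_lesion``; the
    score is ``1 + 9 * exp(-p * L_23S)``, anchored on the large-subunit
    rRNA that dominates the electropherogram.  A blocking-lesion series
    therefore stays pinned at 10 no matter how damaged the RNA is.
    """
    l23s = pool.by_class("rRNA_23S").length
    lam = model.rate_at(level)
    p = lam if model.mechanism == "strand_break" else 0.0
    return 1.0 + 9.0 * math.exp(-p * l23s)


# --------------------------------------------------------------------------
# Default study design: panel, pool and the three-mechanism demo scenario.
# --------------------------------------------------------------------------

def default_panel() -> Panel:
    """The glnA 380/170/120 ratio panel plus amoA and 16S reference assays.

    The 120 bp assay carries a deliberately lower efficiency, reproducing
    the over-unity artifact of short-denominator pairs; reference assays
    run 40 cycles (the index itself always uses the pair's 35-cycle cap).
    """
    assays = {
        a.assay_id: a
        for a in (
            AmpliconAssay("glnA_380", "glnA", 380, efficiency=0.95, max_cycles=35, role="ramp_long"),
            AmpliconAssay("glnA_170", "glnA", 170, efficiency=0.95, max_cycles=35, role="ramp_short"),
            AmpliconAssay("glnA_120", "glnA", 120, efficiency=0.80, max_cycles=35, role="ramp_short"),
            AmpliconAssay("amoA_491", "amoA", 491, efficiency=0.90, max_cycles=40, role="reference_transcript"),
            AmpliconAssay("rrs_143", "16S rRNA", 143, efficiency=0.92, max_cycles=40, role="reference_transcript"),
        )
    }
    pair_defs = (
        ("glnA_380", "glnA_170", "380/170"),
        ("glnA_380", "glnA_120", "380/120"),
    )
    return Panel(assays=assays, pair_defs=pair_defs)


def default_pool() -> TranscriptPool:
    """An environmental-extract pool: two mRNAs plus 16S/23S rRNA.

    rRNA lengths default to 1500 nt (16S) and 2900 nt (23S, roughly twice
    the 16S); baseline Cts place glnA near 20 cycles, the low-abundance
    amoA near 30, and the abundant 16S near 14.
    """
    species = (
        TranscriptSpecies(
            "glnA_mRNA",
            1407,
            "mRNA",
            baseline_ct={"glnA_380": 21.0, "glnA_170": 20.2, "glnA_120": 20.6},
        ),
        TranscriptSpecies("amoA_mRNA", 831, "mRNA", baseline_ct={"amoA_491": 30.2}),
        TranscriptSpecies("rRNA_16S", 1500, "rRNA_16S", baseline_ct={"rrs_143": 14.1}),
        TranscriptSpecies("rRNA_23S", 2900, "rRNA_23S", baseline_ct={}),
    )
    return TranscriptPool(species=species)


def demo_models() -> dict[str, DegradationModel]:
    """Three degradation treatments over a 0/10/45/90-minute series.

    Heat and nuclease fragment the backbone (strand breaks, the nuclease
    harder and faster); UV deposits crosslinks without breaks, the case an
    electrophoretic score cannot see.  Rates are illustrative per-nt event
    intensities, not calibrated to any instrument.
    """
    return {
        "heat": DegradationModel(
            "strand_break",
            level_map={"0min": 0.0, "10min": 2.0e-3, "45min": 3.5e-3, "90min": 5.5e-3},
        ),
        "uv": DegradationModel(
            "blocking_lesion",
            level_map={"0min": 0.0, "10min": 1.8e-3, "45min": 3.5e-3, "90min": 5.2e-3},
        ),
        "nuclease": DegradationModel(
            "strand_break",
            level_map={"0min": 0.0, "10min": 2.2e-3, "45min": 4.0e-3, "90min": 6.0e-3},
        ),
    }
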