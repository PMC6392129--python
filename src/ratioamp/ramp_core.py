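"""The Ratio Amplicon (R_amp) RNA-integrity index.

Two nested amplicons of different length are amplified from the same
transcript (here, bacterial glutamine synthetase *glnA*).  Damage events —
strand breaks or polymerase-blocking lesions — hit the long amplicon more
often than the short one, so the long assay's Ct rises faster as RNA
degrades.  The index rescales the two Cts against the number of cycles the
reaction was run (35 by convention)::

    R_amp = (max_cycles - Ct_long) / (max_cycles - Ct_short)

which is 1 for intact RNA (equal Cts) and falls toward 0 as the long
amplicon is lost.  Cts at or above the cap (or not detected) are clamped
to the cap, so a censored long amplicon yields exactly 0; a censored short
amplicon makes the index the distinguished value :data:`UNDEFINED` (a
fully censored pair carries no integrity information).  Values above 1 can
occur when the short assay's amplification efficiency lags the long one's;
they are reported unclamped and flagged ``OVER_UNITY`` rather than hidden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import DomainError, IncompleteSeriesError
from .qpcr_io import NOT_DETECTED, AggregatedCt, AmpliconAssay, CtObservation, Panel

__all__ = [
    "UNDEFINED",
    "OVER_UNITY",
    "LONG_CENSORED",
    "SHORT_CENSORED",
    "LOW_RIN_INPUT",
    "RIN_QUALITY_THRESHOLD",
    "RampPair",
    "RampResult",
    "build_pairs",
    "compute_ramp",
    "compute_ramp_series",
    "per_replicate_ramps",
    "qc_flags",
    "library_molarity",
]


class _Undefined:
    """Singleton for an index with no defined value (0/0 after clamping)."""

    __slots__ = ()
    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "UNDEFINED"


UNDEFINED = _Undefined()

# QC flags carried on results and passed through to reports.
OVER_UNITY = "OVER_UNITY"
LONG_CENSORED = "LONG_CENSORED"
SHORT_CENSORED = "SHORT_CENSORED"
LOW_RIN_INPUT = "LOW_RIN_INPUT"

#: Electrophoretic-score boundary between 'good' and 'bad' quality RNA.
RIN_QUALITY_THRESHOLD = 7.0


@dataclass(frozen=True)
class RampPair:
    """A long/short amplicon pair sharing one target transcript."""

    long_assay: AmpliconAssay
    short_assay: AmpliconAssay
    label: str

    def __post_init__(self) -> None:
        if self.long_assay.amplicon_length <= self.short_assay.amplicon_length:
            raise DomainError(
                f"pair {self.label!r}: long amplicon "
                f"({self.long_assay.amplicon_length} nt) must be longer than "
                f"short ({self.short_assay.amplicon_length} nt)"
            )
        if self.long_assay.target_gene != self.short_assay.target_gene:
            raise DomainError(
                f"pair {self.label!r}: assays target different genes "
                f"({self.long_assay.target_gene!r} vs "
                f"{self.short_assay.target_gene!r})"
            )

    @property
    def max_cycles(self) -> int:
        """The cycle cap the index uses — the long assay's configured cap."""
        return self.long_assay.max_cycles


def build_pairs(panel: Panel) -> list[RampPair]:
    """Materialize the panel's declared ``(long, short, label)`` pairings."""
    return [
        RampPair(panel[long_id], panel[short_id], label)
        for long_id, short_id, label in panel.pair_defs
    ]


@dataclass(frozen=True)
class RampResult:
    """The integrity index for one sample and one amplicon pair."""

    sample_id: str
    value: float | _Undefined
    ct_long: float
    ct_short: float
    max_cycles: float
    flags: frozenset[str]
    pair: RampPair | None = None
    degradation_level: str | None = None

    @property
    def defined(self) -> bool:
        return not isinstance(self.value, _Undefined)


def compute_ramp(
    ct_long: float | object,
    ct_short: float | object,
    max_cycles: float = 35.0,
    *,
    pair: RampPair | None = None,
    sample_id: str = "",
    degradation_level: str | None = None,
) -> RampResult:
    """Compute the ratio-amplicon index for one Ct pair.

    Either Ct may be :data:`~ratioamp.qpcr_io.NOT_DETECTED`.  Cts at or
    above *max_cycles* are clamped to *max_cycles* before the ratio; the
    corresponding ``LONG_CENSORED`` / ``SHORT_CENSORED`` flag is set.  A
    censored short amplicon (denominator 0) yields :data:`UNDEFINED`.
    A ratio above 1 is returned unclamped with flag ``OVER_UNITY``.
    """
    if max_cycles <= 0:
        raise DomainError("max_cycles must be positive")

    def _clamp(ct: float | object, which: str) -> tuple[float, bool]:
        if ct is NOT_DETECTED:
            return float(max_cycles), True
        ct = float(ct)  # type: ignore[arg-type]
        if not math.isfinite(ct) or ct <= 0:
            raise DomainError(f"{which} Ct must be positive and finite, got {ct}")
        if ct >= max_cycles:
            return float(max_cycles), True
        return ct, False

    long_eff, long_censored = _clamp(ct_long, "long")
    short_eff, short_censored = _clamp(ct_short, "short")

    flags: set[str] = set()
    if long_censored:
        flags.add(LONG_CENSORED)
    if short_censored:
        flags.add(SHORT_CENSORED)

    value: float | _Undefined
    if short_censored:
        value = UNDEFINED
    else:
        value = (max_cycles - long_eff) / (max_cycles - short_eff)
        if value > 1.0:
            flags.add(OVER_UNITY)

    return RampResult(
        sample_id=sample_id,
        value=value,
        ct_long=long_eff,
        ct_short=short_eff,
        max_cycles=float(max_cycles),
        flags=frozenset(flags),
        pair=pair,
        degradation_level=degradation_level,
    )


def compute_ramp_series(
    series: Mapping[str, Mapping[str, AggregatedCt]],
    pair: RampPair,
    level_order: Sequence[str] | None = None,
) -> list[RampResult]:
    """Compute the index along a degradation series from mean Cts.

    *series* maps each degradation level to its per-assay aggregates; the
    result carries one :class:`RampResult` per level in *level_order*
    (default: the mapping's own order).
    """
    levels = list(level_order) if level_order is not None else list(series)
    results: list[RampResult] = []
    for level in levels:
        if level not in series:
            raise IncompleteSeriesError(f"series has no aggregates for level {level!r}")
        aggs = series[level]
        for assay in (pair.long_assay, pair.short_assay):
            if assay.assay_id not in aggs:
                raise IncompleteSeriesError(
                    f"level {level!r} is missing assay {assay.assay_id!r}"
                )
        agg_long = aggs[pair.long_assay.assay_id]
        agg_short = aggs[pair.short_assay.assay_id]
        results.append(
            compute_ramp(
                agg_long.mean_ct,
                agg_short.mean_ct,
                pair.max_cycles,
                pair=pair,
                sample_id=agg_long.sample_id,
                degradation_level=level,
            )
        )
    return results


def per_replicate_ramps(
    long_obs: Sequence[CtObservation],
    short_obs: Sequence[CtObservation],
    pair: RampPair,
) -> dict[int, RampResult]:
    """Replicate-matched index values, for dispersion and group comparisons.

    Replicate *r* of the long assay is paired with replicate *r* of the
    short assay; melt-failed wells and unmatched replicates are skipped.
    Keyed by replicate number.
    """
    short_by_rep = {o.replicate: o for o in short_obs if o.melt_pass}
    out: dict[int, RampResult] = {}
    for o in long_obs:
        if not o.melt_pass or o.replicate not in short_by_rep:
            continue
        s = short_by_rep[o.replicate]
        out[o.replicate] = (
            compute_ramp(
                o.ct,
                s.ct,
                pair.max_cycles,
                pair=pair,
                sample_id=o.sample_id,
                degradation_level=o.degradation_level,
            )
        )
    return out


def qc_flags(
    ramp: RampResult, external_rin: float | None = None
) -> frozenset[str]:
    """Value-derived flags plus ``LOW_RIN_INPUT`` when an external
    electrophoretic score falls strictly below :data:`RIN_QUALITY_THRESHOLD`."""
    flags = set(ramp.flags)
    if external_rin is not None and external_rin < RIN_QUALITY_THRESHOLD:
        flags.add(LOW_RIN_INPUT)
    return frozenset(flags)


def library_molarity(concentration_ng_ul: float, mean_fragment_length: float) -> float:
    """Sequencing-library molarity in nM from concentration and mean length.

    ``molarity = concentration * 1e6 / (660 * length)`` with 660 g/mol per
    base pair of double-stranded DNA.
    """
    if concentration_ng_ul <= 0 or mean_fragment_length <= 0:
        raise DomainError("concentration and fragment length must be positive")
    return concentration_ng_ul * 1e6 / (660.0 * mean_fragment_length)
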