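"""Reading, validation, aggregation and reporting of RT-qPCR Ct data.

The exchange format is a long CSV table with one row per well:
``sample_id, assay_id, replicate, ct[, melt_pass][, degradation_level]``,
where the ``ct`` column holds either a positive decimal cycle-threshold
value or the literal token ``ND`` (not detected).  Assay panels — amplicon
lengths, per-cycle efficiencies, cycle caps and the long/short pairing —
are declared in a small YAML file.

Replicate aggregation supports two censoring policies.  Under ``cap``,
not-detected wells and Cts above the assay's cycle cap are set to the cap
and kept in the mean (an undetected long amplicon then drives the
integrity index to its degraded limit); under ``exclude`` they are dropped.
By default ratio-pair assays are capped and reference transcripts are
excluded, so that censoring informs integrity but never fabricates an
abundance estimate.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .errors import (
    ConfigError,
    CtParseError,
    DomainError,
    MeltCurveError,
    SchemaError,
    UnknownAssayError,
)

__all__ = [
    "NOT_DETECTED",
    "AmpliconAssay",
    "CtObservation",
    "AggregatedCt",
    "Panel",
    "read_panel",
    "read_ct_table",
    "write_ct_table",
    "aggregate_replicates",
    "aggregate_table",
    "default_censor_policy",
    "write_integrity_report",
]

ASSAY_ROLES = ("ramp_long", "ramp_short", "reference_transcript")
CENSOR_POLICIES = ("exclude", "cap")

ND_TOKEN = "ND"


class _NotDetected:
    """Singleton marker for a well with no amplification signal."""

    __slots__ = ()
    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "NOT_DETECTED"


#: Distinguished Ct value for wells that never crossed threshold.
NOT_DETECTED = _NotDetected()


@dataclass(frozen=True)
class AmpliconAssay:
    """One qPCR assay: a primer pair amplifying a region of one transcript.

    Parameters
    ----------
    assay_id : str
        Short unique identifier (e.g. ``glnA_380``).
    target_gene : str
        Transcript the amplicon sits on (e.g. ``glnA``, ``amoA``,
        ``16S rRNA``).
    amplicon_length : int
        Amplicon length in nucleotides; the damage cross-section of the
        assay.
    efficiency : float
        Per-cycle doubling efficiency in ``(0, 1]``; 1.0 means perfect
        doubling each cycle.
    max_cycles : int
        Number of cycles the reaction is run; also the censoring cap.
    role : str
        ``ramp_long``, ``ramp_short`` or ``reference_transcript``.
    """

    assay_id: str
    target_gene: str
    amplicon_length: int
    efficiency: float = 1.0
    max_cycles: int = 35
    role: str = "reference_transcript"

    def __post_init__(self) -> None:
        if self.amplicon_length <= 0:
            raise DomainError(f"{self.assay_id}: amplicon_length must be > 0")
        if not (0.0 < self.efficiency <= 1.0):
            raise DomainError(f"{self.assay_id}: efficiency must be in (0, 1]")
        if self.max_cycles <= 0:
            raise DomainError(f"{self.assay_id}: max_cycles must be > 0")
        if self.role not in ASSAY_ROLES:
            raise ConfigError(
                f"{self.assay_id}: role {self.role!r} not one of {ASSAY_ROLES}"
            )


@dataclass(frozen=True)
class CtObservation:
    """One well of an RT-qPCR plate."""

    sample_id: str
    assay_id: str
    replicate: int
    ct: float | _NotDetected
    melt_pass: bool = True
    degradation_level: str | None = None

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise DomainError("replicate must be a positive integer")
        if not isinstance(self.ct, _NotDetected):
            if not math.isfinite(self.ct) or self.ct <= 0:
                raise DomainError(f"ct must be positive and finite, got {self.ct}")

    @property
    def detected(self) -> bool:
        return not isinstance(self.ct, _NotDetected)


@dataclass(frozen=True)
class AggregatedCt:
    """Replicate-aggregated Ct for one (sample, assay) group."""

    sample_id: str
    assay_id: str
    mean_ct: float
    sd_ct: float
    n_used: int
    n_censored: int
    degradation_level: str | None = None


@dataclass(frozen=True)
class Panel:
    """An assay panel plus its declared long/short ratio pairings.

    ``pair_defs`` holds ``(long_assay_id, short_assay_id, label)`` triples;
    :func:`ratioamp.ramp_core.build_pairs` turns them into validated pairs.
    """

    assays: Mapping[str, AmpliconAssay]
    pair_defs: tuple[tuple[str, str, str], ...] = ()

    def __getitem__(self, assay_id: str) -> AmpliconAssay:
        try:
            return self.assays[assay_id]
        except KeyError:
            raise UnknownAssayError(f"assay_id {assay_id!r} not in panel") from None

    def __contains__(self, assay_id: str) -> bool:
        return assay_id in self.assays

    def by_role(self, role: str) -> list[AmpliconAssay]:
        return [a for a in self.assays.values() if a.role == role]


def read_panel(path: str | Path) -> Panel:
    """Read an assay panel from a YAML file.

    Layout::

        assays:
          - {assay_id: glnA_380, target_gene: glnA, amplicon_length: 380,
             efficiency: 0.95, max_cycles: 35, role: ramp_long}
        pairs:
          - {long: glnA_380, short: glnA_170, label: "380/170"}
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "assays" not in raw:
        raise ConfigError(f"panel file {path} must contain an 'assays' list")
    assays: dict[str, AmpliconAssay] = {}
    for entry in raw["assays"]:
        try:
            assay = AmpliconAssay(**entry)
        except TypeError as exc:
            raise ConfigError(f"bad assay entry {entry!r}: {exc}") from exc
        if assay.assay_id in assays:
            raise ConfigError(f"assay_id {assay.assay_id!r} defined twice")
        assays[assay.assay_id] = assay
    pair_defs = []
    for entry in raw.get("pairs", []):
        try:
            pair_defs.append((entry["long"], entry["short"], entry["label"]))
        except KeyError as exc:
            raise ConfigError(f"pair entry {entry!r} missing key {exc}") from exc
    return Panel(assays=assays, pair_defs=tuple(pair_defs))


_REQUIRED_COLUMNS = ("sample_id", "assay_id", "replicate", "ct")
_OPTIONAL_COLUMNS = ("melt_pass", "degradation_level")
_TRUE_TOKENS = {"true", "1", "yes", "t"}
_FALSE_TOKENS = {"false", "0", "no", "f"}


def _parse_ct(token: str, line_no: int) -> float | _NotDetected:
    token = token.strip()
    if token == ND_TOKEN:
        return NOT_DETECTED
    try:
        value = float(token)
    except ValueError:
        raise CtParseError(
            f"line {line_no}: ct value {token!r} is neither a number nor 'ND'"
        ) from None
    return value


def read_ct_table(path: str | Path, panel: Panel) -> list[CtObservation]:
    """Read a long-format Ct table, validating assay ids against *panel*.

    Row order is preserved.  Errors carry the 1-based file line number.
    """
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in _REQUIRED_COLUMNS:
            if col not in header:
                raise SchemaError(f"missing required column {col!r} in {path}")
        observations: list[CtObservation] = []
        for line_no, row in enumerate(reader, start=2):
            assay_id = row["assay_id"].strip()
            if assay_id not in panel:
                raise UnknownAssayError(
                    f"line {line_no}: assay_id {assay_id!r} not in panel"
                )
            try:
                replicate = int(row["replicate"])
            except ValueError:
                raise CtParseError(
                    f"line {line_no}: replicate {row['replicate']!r} is not an integer"
                ) from None
            melt_token = (row.get("melt_pass") or "").strip().lower()
            if melt_token == "":
                melt_pass = True
            elif melt_token in _TRUE_TOKENS:
                melt_pass = True
            elif melt_token in _FALSE_TOKENS:
                melt_pass = False
            else:
                raise CtParseError(
                    f"line {line_no}: melt_pass {row['melt_pass']!r} is not boolean"
                )
            level = (row.get("degradation_level") or "").strip() or None
            observations.append(
                CtObservation(
                    sample_id=row["sample_id"].strip(),
                    assay_id=assay_id,
                    replicate=replicate,
                    ct=_parse_ct(row["ct"], line_no),
                    melt_pass=melt_pass,
                    degradation_level=level,
                )
            )
    return observations


def write_ct_table(observations: Iterable[CtObservation], path: str | Path) -> None:
    """Write observations back to the CSV dialect :func:`read_ct_table` reads.

    Cts are serialized with :func:`repr` so a write/read round trip is exact.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(list(_REQUIRED_COLUMNS) + list(_OPTIONAL_COLUMNS))
        for obs in observations:
            ct_token = ND_TOKEN if not obs.detected else repr(float(obs.ct))
            writer.writerow(
                [
                    obs.sample_id,
                    obs.assay_id,
                    obs.replicate,
                    ct_token,
                    str(obs.melt_pass).lower(),
                    obs.degradation_level or "",
                ]
            )


def default_censor_policy(assay: AmpliconAssay) -> str:
    """``cap`` for ratio-pair assays, ``exclude`` for reference transcripts."""
    return "cap" if assay.role in ("ramp_long", "ramp_short") else "exclude"


def aggregate_replicates(
    observations: Sequence[CtObservation],
    assay: AmpliconAssay,
    censor_policy: str = "exclude",
) -> AggregatedCt | None:
    """Aggregate technical replicates of one (sample, assay) group.

    Melt-failed replicates are discarded first.  A replicate is *censored*
    when it is not detected or its Ct exceeds ``assay.max_cycles``; under
    policy ``cap`` it enters the mean at the cap, under ``exclude`` it is
    dropped.  Returns ``None`` when censoring leaves no usable replicate
    (the empty-aggregate signal); raises :class:`MeltCurveError` when QC
    leaves nothing to aggregate at all.
    """
    if censor_policy not in CENSOR_POLICIES:
        raise ConfigError(f"censor_policy must be one of {CENSOR_POLICIES}")
    obs = list(observations)
    if not obs:
        raise DomainError("aggregate_replicates requires at least one observation")
    sample_ids = {o.sample_id for o in obs}
    if len(sample_ids) != 1 or any(o.assay_id != assay.assay_id for o in obs):
        raise DomainError(
            "aggregate_replicates expects observations of a single (sample, assay)"
        )
    levels = {o.degradation_level for o in obs}
    level = levels.pop() if len(levels) == 1 else None

    passing = [o for o in obs if o.melt_pass]
    if not passing:
        raise MeltCurveError(
            f"all replicates of ({obs[0].sample_id}, {assay.assay_id}) failed melt QC"
        )

    cap = float(assay.max_cycles)
    values: list[float] = []
    n_censored = 0
    for o in passing:
        censored = (not o.detected) or float(o.ct) > cap
        if censored:
            n_censored += 1
            if censor_policy == "cap":
                values.append(cap)
        else:
            values.append(float(o.ct))
    if not values:
        return None
    arr = np.asarray(values, dtype=float)
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return AggregatedCt(
        sample_id=obs[0].sample_id,
        assay_id=assay.assay_id,
        mean_ct=float(np.mean(arr)),
        sd_ct=sd,
        n_used=len(values),
        n_censored=n_censored,
        degradation_level=level,
    )


def aggregate_table(
    observations: Iterable[CtObservation],
    panel: Panel,
    censor_policy: str | None = None,
) -> dict[tuple[str, str], AggregatedCt]:
    """Aggregate a whole table, grouped by (sample_id, assay_id).

    ``censor_policy=None`` applies the role-based default
    (:func:`default_censor_policy`); groups whose replicates are all
    censored under ``exclude`` are silently absent from the result.
    """
    groups: dict[tuple[str, str], list[CtObservation]] = {}
    for obs in observations:
        if obs.assay_id not in panel:
            raise UnknownAssayError(f"assay_id {obs.assay_id!r} not in panel")
        groups.setdefault((obs.sample_id, obs.assay_id), []).append(obs)
    out: dict[tuple[str, str], AggregatedCt] = {}
    for (sample_id, assay_id), members in groups.items():
        assay = panel[assay_id]
        policy = censor_policy or default_censor_policy(assay)
        agg = aggregate_replicates(members, assay, policy)
        if agg is not None:
            out[(sample_id, assay_id)] = agg
    return out


def write_integrity_report(
    records: Sequence[Mapping[str, object]],
    path: str | Path,
    provenance: Mapping[str, object] | None = None,
) -> None:
    """Write the per-sample integrity summary as TSV plus a JSON sidecar.

    Column order is stable: ``sample_id`` and ``degradation_level`` first,
    remaining columns in first-appearance order, ``flags`` last.  The
    sidecar (``<path>.provenance.json``) records the full provenance the
    caller supplies (panel, policies, seed for simulated data).
    """
    path = Path(path)
    lead = ["sample_id", "degradation_level"]
    tail = ["flags"]
    middle: list[str] = []
    for record in records:
        for key in record:
            if key not in lead and key not in tail and key not in middle:
                middle.append(key)
    columns = lead + middle + (tail if any("flags" in r for r in records) else [])
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(columns)
        for record in records:
            row = []
            for col in columns:
                value = record.get(col, "")
                if isinstance(value, float):
                    value = format(value, ".6g")
                elif isinstance(value, (set, frozenset)):
                    value = ";".join(sorted(value))
                row.append(value)
            writer.writerow(row)
    sidecar = path.parent / (path.name + ".provenance.json")
    with open(sidecar, "w", encoding="utf-8") as fh:
        json.dump(dict(provenance or {}), fh, indent=2, sort_keys=True)
        fh.write("\n")
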