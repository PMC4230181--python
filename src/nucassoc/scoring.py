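"""Frequency scoring of per-nucleus FISH signal configurations.

Turns tables of scored nuclei (one row per nucleus x probe x homolog)
into the frequency metrics used for interphase chromatin analysis:

* **association** — two probed segments touching/overlapping, in cis,
  trans or between homologues; counted per nucleus.
* **elongation** — a segment showing more signals than expected from the
  ploidy level (>2 in 2C, >4 in 4C): a decondensed, stretched fibre.
* **sister-chromatid cohesion** — replicated sisters appearing as one
  fused signal per homologue; counted per homologue in 4C+ nuclei.
* **separation of adjacent segments** — two probes that overlap/abut on
  the chromosome found apart in the nucleus.
* **out-looping** — a segment located outside its chromosome territory.

Scoring accepts categorical flags (as recorded at the microscope) or,
where 2D signal positions are available, a centre-distance threshold;
flags take precedence when both are present.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AmbiguousPloidyError,
    AnnotationError,
    CohesionUndefinedError,
    SchemaError,
    UnscorableError,
)
from .rsd import PLOIDY_LABELS, Relation

__all__ = [
    "SignalObservation",
    "ScoredNucleus",
    "FrequencySummary",
    "SCORED_NUCLEI_COLUMNS",
    "read_scored_nuclei",
    "write_scored_nuclei",
    "nuclei_to_table",
    "association_frequency",
    "elongation_frequency",
    "cohesion_frequency",
    "separation_frequency",
    "outloop_frequency",
    "elongation_signal_threshold",
]

#: Canonical column order of the scored-nuclei TSV schema.
SCORED_NUCLEI_COLUMNS = (
    "nucleus_id",
    "ploidy",
    "tissue",
    "probe_id",
    "homolog_index",
    "signal_count",
    "positions",
    "flags",
)

_KNOWN_FLAG_PREFIXES = ("associated_with:",)
_KNOWN_FLAGS = {"cohesive", "separated_from_adjacent", "outside_CT", "elongated"}


@dataclass(frozen=True)
class SignalObservation:
    """FISH signals of one probe on one (optional) homologue."""

    probe_id: str
    signal_count: int
    homolog_index: int | None = None
    positions: tuple[tuple[float, float], ...] | None = None
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.signal_count < 1:
            raise SchemaError(
                f"probe {self.probe_id}: signal_count must be >= 1 for a detected probe"
            )
        if self.positions is not None and len(self.positions) != self.signal_count:
            raise SchemaError(
                f"probe {self.probe_id}: {len(self.positions)} positions for "
                f"signal_count={self.signal_count}"
            )
        for f in self.flags:
            if f not in _KNOWN_FLAGS and not f.startswith(_KNOWN_FLAG_PREFIXES):
                raise SchemaError(f"unknown flag {f!r} on probe {self.probe_id}")

    def associated_partners(self) -> set[str]:
        return {
            f.split(":", 1)[1] for f in self.flags if f.startswith("associated_with:")
        }


@dataclass(frozen=True)
class ScoredNucleus:
    """One nucleus: ploidy class, tissue and its probe observations."""

    nucleus_id: str
    ploidy_label: str
    tissue: str
    observations: tuple[SignalObservation, ...]

    def __post_init__(self) -> None:
        if self.ploidy_label not in PLOIDY_LABELS:
            raise SchemaError(
                f"nucleus {self.nucleus_id}: unknown ploidy {self.ploidy_label!r}"
            )

    def probe_observations(self, probe_id: str) -> tuple[SignalObservation, ...]:
        return tuple(o for o in self.observations if o.probe_id == probe_id)


@dataclass(frozen=True)
class FrequencySummary:
    """k of n scored units showing a property, as a percentage."""

    metric: str
    k: int
    n: int

    def __post_init__(self) -> None:
        if not (0 <= self.k <= self.n):
            raise ValueError(f"need 0 <= k <= n, got k={self.k}, n={self.n}")

    @property
    def percent(self) -> float:
        return 100.0 * self.k / self.n if self.n else 0.0

    @property
    def percent_display(self) -> float:
        """Percent rounded half-up to one decimal, the reporting convention."""
        return float(
            Decimal(self.percent).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
        )

    def __str__(self) -> str:  # e.g. "association: 13.5% (n = 200)"
        return f"{self.metric}: {self.percent_display}% (n = {self.n})"


# ---------------------------------------------------------------------------
# TSV schema


def _format_positions(obs: SignalObservation) -> str:
    if obs.positions is None:
        return ""
    return "|".join(f"{x:g};{y:g}" for x, y in obs.positions)


def _parse_positions(cell: str, line: int) -> tuple[tuple[float, float], ...] | None:
    if not cell:
        return None
    points = []
    for tok in cell.split("|"):
        parts = tok.split(";")
        if len(parts) != 2:
            raise SchemaError(f"line {line}: malformed position {tok!r} (want 'x;y')")
        try:
            points.append((float(parts[0]), float(parts[1])))
        except ValueError:
            raise SchemaError(f"line {line}: non-numeric position {tok!r}") from None
    return tuple(points)


def nuclei_to_table(nuclei: Iterable[ScoredNucleus]) -> pd.DataFrame:
    """Flatten nuclei into the canonical scored-nuclei table."""
    rows = []
    for nuc in nuclei:
        for obs in nuc.observations:
            rows.append(
                {
                    "nucleus_id": nuc.nucleus_id,
                    "ploidy": nuc.ploidy_label,
                    "tissue": nuc.tissue,
                    "probe_id": obs.probe_id,
                    "homolog_index": "" if obs.homolog_index is None else obs.homolog_index,
                    "signal_count": obs.signal_count,
                    "positions": _format_positions(obs),
                    "flags": ",".join(sorted(obs.flags)),
                }
            )
    return pd.DataFrame(rows, columns=list(SCORED_NUCLEI_COLUMNS))


def write_scored_nuclei(
    nuclei: Iterable[ScoredNucleus] | pd.DataFrame, path: str | Path
) -> None:
    table = nuclei if isinstance(nuclei, pd.DataFrame) else nuclei_to_table(nuclei)
    table.to_csv(path, sep="\t", index=False)


def read_scored_nuclei(
    source: str | Path | pd.DataFrame | _io.IOBase,
) -> list[ScoredNucleus]:
    """Read and validate a scored-nuclei table.

    Accepts a TSV path/handle or an in-memory DataFrame in the same
    schema.  Rows of one nucleus are grouped in input order; malformed
    rows are reported with their (1-based, header-inclusive) line number.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in SCORED_NUCLEI_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    if df.empty:
        return []

    df = df.reset_index(drop=True)
    lines = df.index + 2  # 1-based line numbers counting the header

    seen: set[tuple[str, str, str]] = set()
    nuclei: dict[str, dict] = {}
    for i, row in df.iterrows():
        line = int(lines[i])
        key = (row["nucleus_id"], row["probe_id"], row["homolog_index"])
        if key in seen:
            raise SchemaError(
                f"line {line}: duplicate nucleus/probe/homolog triple {key}"
            )
        seen.add(key)
        if row["ploidy"] not in PLOIDY_LABELS:
            raise SchemaError(f"line {line}: unknown ploidy label {row['ploidy']!r}")
        try:
            count = int(row["signal_count"])
        except ValueError:
            raise SchemaError(
                f"line {line}: non-integer signal_count {row['signal_count']!r}"
            ) from None
        hom = row["homolog_index"]
        try:
            homolog = None if hom == "" else int(hom)
        except ValueError:
            raise SchemaError(f"line {line}: bad homolog_index {hom!r}") from None
        flags = frozenset(f for f in row["flags"].split(",") if f)
        try:
            obs = SignalObservation(
                probe_id=row["probe_id"],
                signal_count=count,
                homolog_index=homolog,
                positions=_parse_positions(row["positions"], line),
                flags=flags,
            )
        except SchemaError as exc:
            raise SchemaError(f"line {line}: {exc}") from None
        rec = nuclei.setdefault(
            row["nucleus_id"],
            {"ploidy": row["ploidy"], "tissue": row["tissue"], "obs": []},
        )
        if rec["ploidy"] != row["ploidy"]:
            raise SchemaError(
                f"line {line}: nucleus {row['nucleus_id']} has conflicting ploidy"
            )
        rec["obs"].append(obs)

    return [
        ScoredNucleus(nid, rec["ploidy"], rec["tissue"], tuple(rec["obs"]))
        for nid, rec in nuclei.items()
    ]


def _coerce_nuclei(nuclei) -> list[ScoredNucleus]:
    if isinstance(nuclei, pd.DataFrame):
        return read_scored_nuclei(nuclei)
    return list(nuclei)


# ---------------------------------------------------------------------------
# metrics


def _min_pair_distance(
    a: Sequence[SignalObservation], b: Sequence[SignalObservation]
) -> float | None:
    pa = [p for o in a if o.positions for p in o.positions]
    pb = [p for o in b if o.positions for p in o.positions]
    if not pa or not pb:
        return None
    pa, pb = np.asarray(pa), np.asarray(pb)
    d = np.hypot(
        pa[:, 0][:, None] - pb[:, 0][None, :], pa[:, 1][:, None] - pb[:, 1][None, :]
    )
    return float(d.min())


def association_frequency(
    nuclei,
    probe_a: str,
    probe_b: str,
    mode: Relation | str = Relation.TRANS,
    distance_threshold: float | str = "use-flags",
) -> FrequencySummary:
    """Per-nucleus frequency of association between two probed segments.

    A nucleus counts as associated when any signal of ``probe_a`` and any
    of ``probe_b`` carry matching ``associated_with`` flags, or — in
    positional mode — lie within ``distance_threshold`` µm of each other.
    Flags take precedence where both are available.  ``n`` counts nuclei
    in which both probes were scored.
    """
    mode = Relation.coerce(mode)
    nuclei = _coerce_nuclei(nuclei)
    positional = isinstance(distance_threshold, (int, float))
    k = n = 0
    any_flags = any_positions = False
    for nuc in nuclei:
        oa, ob = nuc.probe_observations(probe_a), nuc.probe_observations(probe_b)
        if not oa or not ob:
            continue
        n += 1
        any_flags = any_flags or any(o.flags for o in oa + ob)
        flagged = any(probe_b in o.associated_partners() for o in oa) or any(
            probe_a in o.associated_partners() for o in ob
        )
        if flagged:  # a recorded association call wins over positions
            k += 1
            continue
        if positional:
            d = _min_pair_distance(oa, ob)
            if d is not None:
                any_positions = True
                if d <= float(distance_threshold):
                    k += 1
    if n == 0:
        raise UnscorableError(
            f"probes {probe_a}/{probe_b} never co-scored in any nucleus"
        )
    if positional and not (any_positions or any_flags):
        raise UnscorableError(
            f"association of {probe_a}/{probe_b}: neither flags nor positions available"
        )
    return FrequencySummary(f"association_{mode.value}_{probe_a}_{probe_b}", k, n)


def elongation_signal_threshold(ploidy_label: str) -> int:
    """Signal number above which a segment counts as elongated.

    >2 signals in 2C and >4 in 4C; for higher endopolyploid classes the
    convention extrapolates to the ploidy-level signal number.
    """
    return {"2C": 2, "4C": 4, "8C": 8, "16C": 16, "32C": 32, "64C": 64}[ploidy_label]


def _single_ploidy(nuclei: list[ScoredNucleus], metric: str) -> str:
    ploidies = {n.ploidy_label for n in nuclei}
    if len(ploidies) != 1:
        raise AmbiguousPloidyError(
            f"{metric}: input mixes ploidy classes {sorted(ploidies)}; "
            "group nuclei by ploidy first"
        )
    return ploidies.pop()


def elongation_frequency(nuclei, probe: str) -> FrequencySummary:
    """Per-nucleus frequency of chromatin-fibre elongation for one probe.

    A nucleus is elongated when the probe's total signal number exceeds
    the ploidy threshold (>2 in 2C, >4 in 4C) or any observation carries
    the ``elongated`` flag.
    """
    nuclei = _coerce_nuclei(nuclei)
    relevant = [n for n in nuclei if n.probe_observations(probe)]
    if not relevant:
        raise UnscorableError(f"probe {probe} not scored in any nucleus")
    ploidy = _single_ploidy(relevant, "elongation")
    thr = elongation_signal_threshold(ploidy)
    k = 0
    for nuc in relevant:
        obs = nuc.probe_observations(probe)
        total = sum(o.signal_count for o in obs)
        if total > thr or any("elongated" in o.flags for o in obs):
            k += 1
    return FrequencySummary(f"elongation_{probe}_{ploidy}", k, len(relevant))


def cohesion_frequency(nuclei, probe: str) -> FrequencySummary:
    """Per-homologue frequency of sister-chromatid cohesion.

    Defined for replicated (4C and higher) nuclei with recorded homologue
    indices: a homologue is cohesive when its sister signals appear fused
    (signal_count == 1).  ``n`` counts scored homologues.
    """
    nuclei = _coerce_nuclei(nuclei)
    relevant = [n for n in nuclei if n.probe_observations(probe)]
    if not relevant:
        raise UnscorableError(f"probe {probe} not scored in any nucleus")
    ploidy = _single_ploidy(relevant, "cohesion")
    if ploidy == "2C":
        raise CohesionUndefinedError(
            "cohesion is undefined for 2C nuclei (no replicated sisters)"
        )
    k = n = 0
    for nuc in relevant:
        for obs in nuc.probe_observations(probe):
            if obs.homolog_index is None:
                continue
            n += 1
            if obs.signal_count == 1 or "cohesive" in obs.flags:
                k += 1
    if n == 0:
        raise UnscorableError(
            f"cohesion of {probe}: no observations carry a homolog_index"
        )
    return FrequencySummary(f"cohesion_{probe}_{ploidy}", k, n)


def separation_frequency(
    nuclei,
    probe_pair: tuple[str, str],
    annotation: pd.DataFrame | None = None,
    distance_threshold: float | None = None,
) -> FrequencySummary:
    """Frequency at which two adjacent segments are found apart.

    Scored per matched (nucleus, homologue) record pair: separated when
    either record carries ``separated_from_adjacent`` or — with positions
    and a numeric threshold — the closest signal distance exceeds it.
    In 4C tables per-chromatid counting is obtained by entering one row
    per chromatid lineage (distinct homolog_index values).

    ``annotation``: optional BED-derived probe table (from
    :func:`nucassoc.io.read_bed`); when given, the two probes must be
    adjacent/overlapping on the reference or an ``AnnotationError`` is
    raised.
    """
    probe_a, probe_b = probe_pair
    if annotation is not None:
        _require_adjacent(annotation, probe_a, probe_b)
    nuclei = _coerce_nuclei(nuclei)
    k = n = 0
    any_flags = any_positions = False
    for nuc in nuclei:
        oa = {o.homolog_index: o for o in nuc.probe_observations(probe_a)}
        ob = {o.homolog_index: o for o in nuc.probe_observations(probe_b)}
        for hom in sorted(set(oa) & set(ob), key=lambda h: (h is None, h)):
            a, b = oa[hom], ob[hom]
            n += 1
            any_flags = any_flags or bool(a.flags or b.flags)
            if "separated_from_adjacent" in a.flags | b.flags:
                k += 1
            elif distance_threshold is not None:
                d = _min_pair_distance([a], [b])
                if d is not None:
                    any_positions = True
                    if d > distance_threshold:
                        k += 1
    if n == 0:
        raise UnscorableError(
            f"probes {probe_a}/{probe_b} share no scored homologue records"
        )
    if distance_threshold is not None and not (any_positions or any_flags):
        raise UnscorableError(
            f"separation of {probe_a}/{probe_b}: neither flags nor positions available"
        )
    return FrequencySummary(f"separation_{probe_a}_{probe_b}", k, n)


def _require_adjacent(annotation: pd.DataFrame, probe_a: str, probe_b: str) -> None:
    by_name = annotation.set_index("name")
    for p in (probe_a, probe_b):
        if p not in by_name.index:
            raise AnnotationError(f"probe {p} absent from the annotation")
    ra, rb = by_name.loc[probe_a], by_name.loc[probe_b]
    if ra["chrom"] != rb["chrom"]:
        raise AnnotationError(f"{probe_a} and {probe_b} lie on different chromosomes")
    # adjacent = overlapping or abutting intervals (half-open coordinates)
    if ra["start"] > rb["end"] or rb["start"] > ra["end"]:
        raise AnnotationError(
            f"{probe_a} and {probe_b} are not adjacent on {ra['chrom']}"
        )


def outloop_frequency(
    nuclei, probe: str, territory_probe: str | None = None
) -> FrequencySummary:
    """Per-nucleus frequency of a segment lying outside its territory.

    Requires nuclei scored with the ``outside_CT`` flag (relative to the
    painted ``territory_probe``, which is recorded for provenance only).
    """
    nuclei = _coerce_nuclei(nuclei)
    k = n = 0
    any_flags = False
    for nuc in nuclei:
        obs = nuc.probe_observations(probe)
        if not obs:
            continue
        n += 1
        any_flags = any_flags or any(o.flags for o in obs)
        if any("outside_CT" in o.flags for o in obs):
            k += 1
    if n == 0:
        raise UnscorableError(f"probe {probe} not scored in any nucleus")
    if not any_flags and k == 0:
        raise UnscorableError(
            f"out-looping of {probe}: no observation carries flags; the "
            "outside_CT call cannot be derived from positions"
        )
    suffix = f"_vs_{territory_probe}" if territory_probe else ""
    return FrequencySummary(f"outloop_{probe}{suffix}", k, n)
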