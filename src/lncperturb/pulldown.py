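"""Sense/antisense RNA pull-down enrichment scoring.

An RNA pull-down assay incubates a biotinylated sense RNA probe (and its
reverse-complement antisense control) with cell lysate; bound proteins are
identified by mass spectrometry and semi-quantified by peptide spectrum
counts (PSM counts) in three replicates per arm.  A protein is a candidate
interactor when its sense-arm counts exceed its antisense-arm counts:

* **unique binding** — PSM counts in all three sense replicates and none in
  any antisense replicate;
* **enriched binding** — mean sense / mean antisense fold change >= 2.

Proteins evenly split between arms (fold change of exactly 1), enriched in
the antisense arm (< 1), below the fold-change threshold, or with
inconsistent sense replicates are excluded.

The fold change divides the mean sense count by ``max(mean antisense,
denominator_floor)`` with a default floor of one pseudo-count, so that a
single stray antisense spectrum does not explode the ratio.  Rows where the
floor changed the ratio carry both the floored and the raw value and an
``inconsistent_with_floor`` flag when the two disagree at table precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "PulldownRecord",
    "EnrichmentCall",
    "UNIQUE",
    "CATEGORIES",
    "compute_enrichment",
    "classify_protein",
    "score_table",
    "rank_candidates",
    "read_pulldown_table",
    "write_enrichment_table",
    "render_enrichment",
    "nuclear_table_path",
    "cytoplasmic_table_path",
]

#: Sentinel for unique binding (no antisense spectra at all); rendered "N/A".
UNIQUE = "unique-binding"

CATEGORIES = (
    "unique",
    "enriched",
    "excluded_even",
    "excluded_antisense",
    "excluded_low_fc",
    "excluded_inconsistent",
)


class PulldownError(ValueError):
    """Malformed or degenerate pull-down input."""


@dataclass(frozen=True)
class PulldownRecord:
    """One protein's replicate peptide spectrum counts from both arms."""

    protein_id: str
    mass_kda: float
    sense_counts: tuple[int, int, int]
    antisense_counts: tuple[int, int, int]

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise PulldownError("protein_id must be non-empty")
        if not (self.mass_kda > 0):
            raise PulldownError(f"{self.protein_id}: mass_kda must be positive")
        for arm, counts in (("sense", self.sense_counts), ("antisense", self.antisense_counts)):
            if len(counts) != 3:
                raise PulldownError(
                    f"{self.protein_id}: expected exactly 3 {arm} replicates, got {len(counts)}"
                )
            if any((not isinstance(c, (int,)) or isinstance(c, bool)) for c in counts):
                raise PulldownError(f"{self.protein_id}: {arm} counts must be integers")
            if any(c < 0 for c in counts):
                raise PulldownError(f"{self.protein_id}: negative {arm} count")
        if not any(self.sense_counts) and not any(self.antisense_counts):
            raise PulldownError(f"{self.protein_id}: all six counts are zero (degenerate record)")


@dataclass(frozen=True)
class EnrichmentCall:
    """Scored (and optionally classified) pull-down result for one protein.

    ``enrichment`` is the floored-denominator fold change or the
    :data:`UNIQUE` sentinel; ``enrichment_raw`` is the unfloored ratio
    (``inf`` when the antisense mean is zero).  ``inconsistent_with_floor``
    marks rows where flooring changed the one-decimal rendering, i.e. where
    a published ratio computed without the floor would disagree.
    """

    protein_id: str
    mean_sense: float
    mean_antisense: float
    enrichment: float | str
    enrichment_raw: float
    inconsistent_with_floor: bool = False
    category: str | None = None

    @property
    def is_unique(self) -> bool:
        return self.enrichment == UNIQUE


def _mean(counts: Sequence[int]) -> float:
    return sum(counts) / len(counts)


def render_enrichment(value: float | str, ndigits: int = 1) -> str:
    """Render a fold change for table output: one decimal, half-up; unique -> 'N/A'."""
    if value == UNIQUE:
        return "N/A"
    if math.isinf(value):
        return "inf"
    q = Decimal(1).scaleb(-ndigits)
    return str(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def compute_enrichment(record: PulldownRecord, denominator_floor: float = 1.0) -> EnrichmentCall:
    """Average each arm's replicates and form the sense/antisense fold change.

    A protein with spectra in every sense replicate and none in any antisense
    replicate gets the unique-binding sentinel instead of a ratio.  Otherwise
    the denominator is floored at ``denominator_floor`` (default 1).
    """
    if denominator_floor < 0:
        raise PulldownError("denominator_floor must be >= 0")
    ms = _mean(record.sense_counts)
    ma = _mean(record.antisense_counts)
    if ma == 0 and all(c > 0 for c in record.sense_counts):
        return EnrichmentCall(record.protein_id, ms, ma, UNIQUE, math.inf)
    raw = ms / ma if ma > 0 else math.inf
    denom = max(ma, denominator_floor)
    floored = ms / denom if denom > 0 else math.inf
    flagged = (
        math.isfinite(floored)
        and floored != raw
        and (not math.isfinite(raw) or render_enrichment(raw) != render_enrichment(floored))
    )
    return EnrichmentCall(record.protein_id, ms, ma, floored, raw, flagged)


def _sense_cv(counts: Sequence[int]) -> float:
    m = _mean(counts)
    if m == 0:
        return 0.0
    var = sum((c - m) ** 2 for c in counts) / (len(counts) - 1)
    return math.sqrt(var) / m


def classify_protein(
    call: EnrichmentCall,
    record: PulldownRecord,
    fc_threshold: float = 2.0,
    cv_threshold: float = 0.6,
) -> EnrichmentCall:
    """Assign the binding category for a scored protein.

    Order of evaluation: unique sentinel; even split (fold change exactly 1
    after flooring) or antisense enrichment (< 1); sub-threshold fold change;
    replicate inconsistency (sense coefficient of variation above
    ``cv_threshold``, or a zero among otherwise positive sense replicates);
    else enriched.
    """
    if call.category is not None:
        raise PulldownError(f"{call.protein_id}: category already set (classification is one-shot)")
    if call.protein_id != record.protein_id:
        raise PulldownError("call/record protein_id mismatch")
    if call.is_unique:
        cat = "unique"
    elif call.enrichment == 1:
        cat = "excluded_even"
    elif call.enrichment < 1:
        cat = "excluded_antisense"
    elif call.enrichment < fc_threshold:
        cat = "excluded_low_fc"
    elif _sense_cv(record.sense_counts) > cv_threshold or (
        any(c == 0 for c in record.sense_counts) and any(c > 0 for c in record.sense_counts)
    ):
        cat = "excluded_inconsistent"
    else:
        cat = "enriched"
    return replace(call, category=cat)


def score_table(
    records: Iterable[PulldownRecord],
    denominator_floor: float = 1.0,
    fc_threshold: float = 2.0,
    cv_threshold: float = 0.6,
) -> list[EnrichmentCall]:
    """Score and classify every record (the full compute+classify chain)."""
    return [
        classify_protein(compute_enrichment(r, denominator_floor), r, fc_threshold, cv_threshold)
        for r in records
    ]


def filter_allowlist(
    calls: Iterable[EnrichmentCall], allowlist: Iterable[str]
) -> list[EnrichmentCall]:
    """Restrict calls to proteins on a user-supplied allow-list.

    Prioritizing candidates with known interferon/antiviral associations is
    a literature judgement, so it is never applied by default: callers pass
    their own curated list.
    """
    allowed = set(allowlist)
    return [c for c in calls if c.protein_id in allowed]


def rank_candidates(calls: Iterable[EnrichmentCall]) -> list[EnrichmentCall]:
    """Candidate table ordering: unique rows first (descending mean sense
    count), then enriched rows by descending fold change; ties alphabetical.
    Excluded rows are dropped."""
    calls = list(calls)
    if any(c.category is None for c in calls):
        raise PulldownError("rank_candidates requires classified calls")
    uniques = [c for c in calls if c.category == "unique"]
    enriched = [c for c in calls if c.category == "enriched"]
    uniques.sort(key=lambda c: (-c.mean_sense, c.protein_id))
    enriched.sort(key=lambda c: (-float(c.enrichment), c.protein_id))
    return uniques + enriched


# ---------------------------------------------------------------------------
# Table I/O

_COLUMNS = ["protein_id", "mass_kda", "s1", "s2", "s3", "a1", "a2", "a3"]


def read_pulldown_table(path: str | Path) -> list[PulldownRecord]:
    """Read a tab-separated pull-down table (header row, '#' comments ignored)."""
    path = Path(path)
    records: list[PulldownRecord] = []
    seen: set[str] = set()
    header: list[str] | None = None
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields]
                missing = [c for c in _COLUMNS if c not in header]
                if missing:
                    raise PulldownError(f"{path}:{lineno}: missing column(s) {missing}")
                continue
            row = dict(zip(header, (f.strip() for f in fields)))
            pid = row.get("protein_id", "")
            if pid in seen:
                raise PulldownError(f"{path}:{lineno}: duplicate protein_id {pid!r}")
            seen.add(pid)
            counts = []
            for col in ("s1", "s2", "s3", "a1", "a2", "a3"):
                raw = row.get(col, "")
                try:
                    counts.append(int(raw))
                except (TypeError, ValueError):
                    raise PulldownError(
                        f"{path}:{lineno} ({pid}): column {col} value {raw!r} is not an integer"
                    ) from None
            try:
                mass = float(row["mass_kda"])
            except ValueError:
                raise PulldownError(f"{path}:{lineno} ({pid}): bad mass_kda {row['mass_kda']!r}") from None
            records.append(PulldownRecord(pid, mass, tuple(counts[:3]), tuple(counts[3:])))
    if header is None:
        raise PulldownError(f"{path}: empty file (no header)")
    return records


def write_enrichment_table(
    calls: Iterable[EnrichmentCall],
    records: Iterable[PulldownRecord],
    path: str | Path,
) -> None:
    """Write a scored table mirroring the published layout: id, mass, the six
    replicate counts, the rendered fold change ('N/A' for unique) and category."""
    by_id = {r.protein_id: r for r in records}
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("\t".join(_COLUMNS + ["enrichment", "category"]) + "\n")
        for call in calls:
            rec = by_id[call.protein_id]
            cells = [
                rec.protein_id,
                f"{rec.mass_kda:g}",
                *(str(c) for c in rec.sense_counts),
                *(str(c) for c in rec.antisense_counts),
                render_enrichment(call.enrichment),
                call.category or "",
            ]
            fh.write("\t".join(cells) + "\n")


def _data_path(name: str) -> Path:
    return Path(__file__).parent / "data" / name


def nuclear_table_path() -> Path:
    """Bundled nuclear-lysate pull-down PSM count table."""
    return _data_path("pulldown_nuclear.tsv")


def cytoplasmic_table_path() -> Path:
    """Bundled cytoplasmic-lysate pull-down PSM count table."""
    return _data_path("pulldown_cytoplasmic.tsv")
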