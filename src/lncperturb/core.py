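"""IFN-responsive gene filtering and the knockdown/overexpression core set.

After per-experiment differential-expression modelling, genes pass through
two filters mirroring the study workflow:

1. **IFN-responsive** — the control line's treatment response exceeds a
   log2FC of 1.25 (strict, signed: the filter selects genes up-regulated by
   interferon) at a given dose, per experiment.
2. **Perturbation hit** — at a dose where the gene is IFN-responsive in
   that experiment, the contrast-of-contrasts ("KD effect" / "OE effect")
   has raw p below alpha for any (default) or all knockdown lines, or for
   the single overexpression line.

Genes responsive in at least one experiment are then partitioned into
KD-only, OE-only, both (the *core* set consistently regulated by the
perturbation) and neither.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .counts import DesignError
from .de import ContrastResult

__all__ = [
    "CoreGeneReport",
    "ifn_responsive",
    "perturbation_hits",
    "core_partition",
    "figure_matrix",
    "core_report",
]

PARTITIONS = ("KD_only", "OE_only", "both", "neither")


@dataclass(frozen=True)
class CoreGeneReport:
    """Per-gene responsiveness/hit flags and the resulting partition.

    ``table`` rows are the genes responsive in at least one experiment,
    ordered by descending mean absolute effect log2FC; columns include
    ``kd_hit``, ``oe_hit`` and ``partition``.
    """

    table: pd.DataFrame

    def genes(self, partition: str) -> list[str]:
        if partition not in PARTITIONS:
            raise ValueError(f"unknown partition {partition!r}")
        return list(self.table.index[self.table["partition"] == partition])

    @property
    def core_genes(self) -> list[str]:
        """Genes differentially responding after both KD and OE (the core set)."""
        return self.genes("both")

    def partition_counts(self) -> dict[str, int]:
        return {p: int((self.table["partition"] == p).sum()) for p in PARTITIONS}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_responsive": int(self.table.shape[0]),
            "n_hit": int((self.table["partition"] != "neither").sum()),
            "partition_counts": self.partition_counts(),
            "core_genes": self.core_genes,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def ifn_responsive(
    control_responses: dict[tuple[str, str], ContrastResult],
    threshold_log2fc: float = 1.25,
    signed: bool = True,
) -> pd.DataFrame:
    """Flag genes whose control-line response log2FC exceeds the threshold.

    ``control_responses`` maps (experiment, dose) to the control line's
    response contrast.  The comparison is strict; with ``signed`` (default)
    only positive responses qualify, otherwise ``|log2FC|`` is used.
    Returns a boolean frame, genes x "(experiment, dose)" columns.
    """
    if not control_responses:
        raise DesignError("no control response contrasts supplied")
    cols = {}
    for (experiment, dose), res in control_responses.items():
        fc = res.log2fc if signed else res.log2fc.abs()
        cols[(experiment, dose)] = fc > threshold_log2fc
    flags = pd.DataFrame(cols)
    flags.columns = pd.MultiIndex.from_tuples(flags.columns, names=["experiment", "dose"])
    return flags.fillna(False)


def perturbation_hits(
    effect_results: dict[tuple[str, str, str], ContrastResult],
    responsive: pd.DataFrame,
    kd_lines: tuple[str, ...],
    oe_lines: tuple[str, ...],
    alpha: float = 0.05,
    kd_lines_rule: str = "any",
) -> pd.DataFrame:
    """KD/OE hit flags: significant effect at a dose where the gene is responsive.

    ``effect_results`` maps (experiment, line, dose) to the effect contrast
    of that perturbed line vs the control.  A gene is a KD hit when, at some
    dose where it is IFN-responsive in the KD experiment, the effect raw p
    is below ``alpha`` for any (or all, per ``kd_lines_rule``) of
    ``kd_lines``; an OE hit likewise over ``oe_lines``.  Only ``kd_lines`` /
    ``oe_lines`` participate — positive-control lines are ignored.
    """
    if not 0 < alpha < 1:
        raise DesignError("alpha must be in (0, 1)")
    if kd_lines_rule not in ("any", "all"):
        raise DesignError("kd_lines_rule must be 'any' or 'all'")
    index = next(iter(effect_results.values())).table.index

    def hit_for(experiment: str, lines: tuple[str, ...], rule: str) -> pd.Series:
        hit = pd.Series(False, index=index)
        if not lines:
            return hit
        doses = sorted({d for (e, _, d) in effect_results if e == experiment})
        for dose in doses:
            if (experiment, dose) not in responsive.columns:
                continue
            resp = responsive[(experiment, dose)].reindex(index, fill_value=False)
            sigs = []
            for line in lines:
                key = (experiment, line, dose)
                if key not in effect_results:
                    raise DesignError(f"missing effect contrast for {key}")
                sigs.append(effect_results[key].p_raw.reindex(index) < alpha)
            sig = pd.concat(sigs, axis=1)
            combined = sig.any(axis=1) if rule == "any" else sig.all(axis=1)
            hit |= resp & combined
        return hit

    return pd.DataFrame(
        {
            "kd_hit": hit_for("KD", kd_lines, kd_lines_rule),
            "oe_hit": hit_for("OE", oe_lines, "any"),
        }
    )


def core_partition(
    hits: pd.DataFrame,
    responsive: pd.DataFrame,
    effect_results: dict[tuple[str, str, str], ContrastResult] | None = None,
) -> CoreGeneReport:
    """Partition responsive genes by where their IFN response was altered.

    Only genes responsive in at least one (experiment, dose) are reported.
    Ordering is by descending mean absolute effect log2FC (when effect
    contrasts are supplied), ties by gene id.
    """
    any_responsive = responsive.any(axis=1).reindex(hits.index, fill_value=False)
    table = hits.loc[any_responsive].copy()
    if table.empty:
        table["partition"] = pd.Series(dtype=str)
        table["mean_abs_effect"] = pd.Series(dtype=float)
        return CoreGeneReport(table)
    table["partition"] = np.select(
        [
            table["kd_hit"] & table["oe_hit"],
            table["kd_hit"],
            table["oe_hit"],
        ],
        ["both", "KD_only", "OE_only"],
        default="neither",
    )
    for (exp, dose) in responsive.columns:
        table[f"responsive_{exp}_{dose}"] = responsive[(exp, dose)].reindex(table.index)
    if effect_results:
        eff = pd.concat(
            {f"{e}:{l}:{d}": r.log2fc for (e, l, d), r in effect_results.items()}, axis=1
        ).reindex(table.index)
        table["mean_abs_effect"] = eff.abs().mean(axis=1)
    else:
        table["mean_abs_effect"] = 0.0
    order = sorted(table.index, key=lambda g: (-table.at[g, "mean_abs_effect"], g))
    return CoreGeneReport(table.loc[order])


def figure_matrix(
    report: CoreGeneReport,
    response_results: dict[tuple[str, str, str], ContrastResult],
    effect_results: dict[tuple[str, str, str], ContrastResult],
) -> pd.DataFrame:
    """Heatmap-ready matrix: per-line per-dose IFN-response log2FCs, then
    per perturbed-line per-dose effect log2FCs, for the reported genes.

    Values are copied from the contrast tables verbatim (no recomputation).
    ``response_results`` / ``effect_results`` map (experiment, line, dose)
    to contrasts.
    """
    if report.table.empty:
        return pd.DataFrame()
    genes = report.table.index
    cols = {}
    for (exp, line, dose), res in response_results.items():
        cols[f"IFN_response:{exp}:{line}:{dose}"] = res.log2fc.reindex(genes)
    for (exp, line, dose), res in effect_results.items():
        cols[f"effect:{exp}:{line}:{dose}"] = res.log2fc.reindex(genes)
    return pd.DataFrame(cols, index=genes)


def core_report(
    control_responses: dict[tuple[str, str], ContrastResult],
    effect_results: dict[tuple[str, str, str], ContrastResult],
    kd_lines: tuple[str, ...],
    oe_lines: tuple[str, ...],
    threshold_log2fc: float = 1.25,
    alpha: float = 0.05,
    kd_lines_rule: str = "any",
    signed: bool = True,
) -> CoreGeneReport:
    """End-to-end: responsiveness filter + hit calls + partition."""
    responsive = ifn_responsive(control_responses, threshold_log2fc, signed=signed)
    hits = perturbation_hits(
        effect_results, responsive, kd_lines, oe_lines, alpha=alpha, kd_lines_rule=kd_lines_rule
    )
    return core_partition(hits, responsive, effect_results)
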