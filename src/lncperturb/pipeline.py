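"""End-to-end perturbation-response analysis over the two-experiment design.

``run_perturbation_analysis`` chains the standard steps: expression filter,
TMM normalization, per-experiment trend-moderated linear models, all
response / effect / baseline contrasts, the IFN-responsiveness filter and
the KD/OE core-gene partition.  The returned object keeps every
intermediate so nothing needs recomputation downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .core import CoreGeneReport, core_report, figure_matrix
from .counts import CountMatrix, DesignError, NormalizedExpression, SampleDesign, normalize
from .de import ContrastResult, ModeratedFitResults, ModeratedLinearModel

__all__ = ["PerturbationAnalysis", "run_perturbation_analysis"]

#: Perturbed lines treated as positive controls, excluded from hit calling.
DEFAULT_POSITIVE_CONTROLS = ("STAT1g1",)


@dataclass
class PerturbationAnalysis:
    """Everything the perturbation-response pipeline computes."""

    expression: NormalizedExpression
    fits: dict[str, ModeratedFitResults]
    responses: dict[tuple[str, str, str], ContrastResult]      # (experiment, line, dose)
    effects: dict[tuple[str, str, str], ContrastResult]        # (experiment, line, dose)
    baselines: dict[tuple[str, str], ContrastResult]           # (experiment, line)
    report: CoreGeneReport
    kd_lines: tuple[str, ...]
    oe_lines: tuple[str, ...]

    @property
    def control_responses(self) -> dict[tuple[str, str], ContrastResult]:
        return {
            (exp, dose): res
            for (exp, line, dose), res in self.responses.items()
            if line == "control"
        }

    def heatmap_matrix(self) -> pd.DataFrame:
        return figure_matrix(self.report, self.responses, self.effects)

    def write(self, outdir: str | Path) -> None:
        """Write contrast TSVs, the core report and the heatmap matrix."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for group, results in (("response", self.responses), ("effect", self.effects)):
            for (exp, line, dose), res in results.items():
                res.table.rename_axis("gene_id").to_csv(
                    outdir / f"{group}_{exp}_{line}_{dose}.tsv", sep="\t"
                )
        for (exp, line), res in self.baselines.items():
            res.table.rename_axis("gene_id").to_csv(
                outdir / f"baseline_{exp}_{line}.tsv", sep="\t"
            )
        import yaml

        manifest = {
            "responses": [f"{e}:{l}:{d}" for (e, l, d) in sorted(self.responses)],
            "effects": [f"{e}:{l}:{d}" for (e, l, d) in sorted(self.effects)],
            "baselines": [f"{e}:{l}" for (e, l) in sorted(self.baselines)],
            "kd_lines": list(self.kd_lines),
            "oe_lines": list(self.oe_lines),
        }
        (outdir / "contrasts.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
        self.report.table.rename_axis("gene_id").to_csv(outdir / "core_report.tsv", sep="\t")
        self.report.to_json(outdir / "partition.json")
        self.heatmap_matrix().rename_axis("gene_id").to_csv(
            outdir / "heatmap_matrix.tsv", sep="\t"
        )


def run_perturbation_analysis(
    matrix: CountMatrix,
    design: SampleDesign,
    min_count: int = 30,
    min_samples: int = 3,
    prior_count: float = 3.0,
    trend_span: float = 0.5,
    threshold_log2fc: float = 1.25,
    alpha: float = 0.05,
    kd_lines_rule: str = "any",
    positive_controls: tuple[str, ...] = DEFAULT_POSITIVE_CONTROLS,
) -> PerturbationAnalysis:
    """Run the full filter / normalize / model / contrast / partition chain.

    ``positive_controls`` names perturbed lines (e.g. a STAT1 knockdown)
    whose contrasts are computed but never contribute to hit calling.
    """
    design.check_against(matrix)
    expr = normalize(
        matrix, design, min_count=min_count, min_samples=min_samples, prior_count=prior_count
    )
    fits: dict[str, ModeratedFitResults] = {}
    responses: dict[tuple[str, str, str], ContrastResult] = {}
    effects: dict[tuple[str, str, str], ContrastResult] = {}
    baselines: dict[tuple[str, str], ContrastResult] = {}
    kd_lines: list[str] = []
    oe_lines: list[str] = []
    for exp in design.experiments():
        sub = design.table[design.table["experiment"] == exp]
        lines = sorted(sub["perturbation"].unique())
        if "control" not in lines:
            raise DesignError(f"experiment {exp!r} has no 'control' line")
        doses = [d for d in ("low", "high") if (sub["dose"] == d).any()]
        fit = ModeratedLinearModel.from_design_sheet(expr, design, experiment=exp).fit(
            trend_span=trend_span
        )
        fits[exp] = fit
        for line in lines:
            for dose in doses:
                responses[(exp, line, dose)] = fit.response(line, dose)
                if line != "control":
                    effects[(exp, line, dose)] = fit.effect(line, "control", dose)
            if line != "control":
                baselines[(exp, line)] = fit.baseline(line, "control")
                if line in positive_controls:
                    continue
                (kd_lines if exp == "KD" else oe_lines).append(line)
    report = core_report(
        {(e, d): r for (e, l, d), r in responses.items() if l == "control"},
        effects,
        kd_lines=tuple(kd_lines),
        oe_lines=tuple(oe_lines),
        threshold_log2fc=threshold_log2fc,
        alpha=alpha,
        kd_lines_rule=kd_lines_rule,
    )
    return PerturbationAnalysis(
        expression=expr,
        fits=fits,
        responses=responses,
        effects=effects,
        baselines=baselines,
        report=report,
        kd_lines=tuple(kd_lines),
        oe_lines=tuple(oe_lines),
    )
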