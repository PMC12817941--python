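"""Ground-truthed synthetic inputs for the pull-down and RNA-seq pipelines.

Two generators, both fully seeded:

``simulate_pulldown``
    Poisson peptide-spectrum-count tables with planted *background* proteins
    (equal sense/antisense means), *enriched* proteins (sense mean inflated
    by a known factor) and *unique* proteins (antisense identically zero;
    sense counts drawn zero-truncated so the unique-binding definition is
    satisfiable by construction).

``simulate_counts``
    Negative-binomial gene x sample count matrices under the study's
    two-experiment factorial design: a knockdown (KD) experiment with a
    control gRNA line, two lncRNA KD lines and a STAT1 KD line (positive
    control), and an overexpression (OE) experiment with a control line and
    one OE line; each line treated with mock or a low (1 ng/mL) or high
    (10 ng/mL) interferon-beta dose in triplicate.  Counts follow
    ``NB(mean = libsize * 2**(b_g + x_s . beta_g), var = mu + phi * mu**2)``
    with a single shared dispersion ``phi``.  Planted structure:

    * interferon-stimulated genes (ISGs) respond to dose with log2FC drawn
      from ``isg_log2fc_range`` (high dose >= low dose);
    * *core* genes have that response reduced by ``perturbation_delta``
      (log2) in both lncRNA KD lines and increased by the same amount in
      the OE line; KD-only / OE-only genes are modulated in one experiment;
    * the STAT1 KD line attenuates every ISG response by a common factor;
    * non-ISG genes have no treatment effect.

The returned :class:`SimTruth` carries every planted flag and the true
log2 fold change of every (line, dose) response, so downstream recovery can
be scored exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .counts import CountMatrix, SampleDesign
from .pulldown import PulldownRecord

__all__ = [
    "PulldownSimSpec",
    "RnaSeqSimSpec",
    "SimTruth",
    "simulate_pulldown",
    "simulate_counts",
    "write_simulation",
    "KD_LINES",
    "STAT1_LINE",
    "OE_LINE",
]

#: Perturbed lines of the knockdown experiment targeting the lncRNA.
KD_LINES = ("KDg1", "KDg2")
#: STAT1 knockdown positive-control line (attenuates all ISG responses).
STAT1_LINE = "STAT1g1"
#: Overexpression-experiment perturbed line.
OE_LINE = "OE"


class SimSpecError(ValueError):
    """Invalid simulation parameters."""


@dataclass(frozen=True)
class PulldownSimSpec:
    """Parameters of the peptide-count simulation."""

    n_background: int = 50
    n_unique: int = 5
    n_enriched: int = 10
    base_mean: float = 20.0
    enrichment_factor: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_background, self.n_unique, self.n_enriched) < 0:
            raise SimSpecError("protein counts must be >= 0")
        if self.base_mean <= 0:
            raise SimSpecError("base_mean must be positive")
        if self.enrichment_factor <= 2:
            raise SimSpecError("enrichment_factor must exceed the FC threshold of 2")


@dataclass(frozen=True)
class RnaSeqSimSpec:
    """Parameters of the factorial RNA-seq count simulation.

    Defaults describe a 2,000-gene panel at bulk sequencing depth with 100
    ISGs, of which 15 are core (modulated in both experiments), 15 KD-only
    and 5 OE-only.
    """

    n_genes: int = 2000
    n_isg: int = 100
    n_core: int = 15
    n_kd_only: int = 15
    n_oe_only: int = 5
    replicates: int = 3
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 2.0
    isg_baseline_log2_mean: float = 8.0
    isg_baseline_log2_sd: float = 1.0
    dispersion: float = 0.05
    isg_log2fc_range: tuple[float, float] = (1.5, 6.0)
    perturbation_delta: float = 1.0
    stat1_attenuation: float = 0.5
    libsize_range: tuple[float, float] = (0.5, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.n_core + self.n_kd_only + self.n_oe_only <= self.n_isg <= self.n_genes):
            raise SimSpecError("need n_core + n_kd_only + n_oe_only <= n_isg <= n_genes")
        if self.replicates < 2:
            raise SimSpecError("every design cell needs >= 2 replicates")
        if self.dispersion <= 0:
            raise SimSpecError("dispersion must be positive")
        lo, hi = self.isg_log2fc_range
        if not (0 < lo <= hi):
            raise SimSpecError("isg_log2fc_range must be positive and ordered")
        lo, hi = self.libsize_range
        if not (0 < lo <= hi):
            raise SimSpecError("libsize_range must be positive and ordered")


@dataclass(frozen=True)
class SimTruth:
    """Planted ground truth accompanying a simulated dataset."""

    genes: pd.DataFrame | None = None       # flags + per-gene parameters
    responses: pd.DataFrame | None = None   # true log2FC per (gene, line, dose)
    proteins: pd.DataFrame | None = None    # protein_id -> planted category
    checksum: str | None = None             # links truth to its data table

    def to_json(self, path: str | Path) -> None:
        payload = {
            "checksum": self.checksum,
            "genes": None if self.genes is None else self.genes.reset_index().to_dict("list"),
            "responses": None
            if self.responses is None
            else self.responses.reset_index().to_dict("list"),
            "proteins": None
            if self.proteins is None
            else self.proteins.reset_index().to_dict("list"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _checksum_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv().encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Pull-down tables


def _truncated_poisson(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    """Poisson draws conditioned on being positive (resampling zeros)."""
    out = rng.poisson(mean, size)
    while (zero := out == 0).any():
        out[zero] = rng.poisson(mean, int(zero.sum()))
    return out


def simulate_pulldown(spec: PulldownSimSpec) -> tuple[list[PulldownRecord], SimTruth]:
    """Simulate a replicate PSM-count table with planted binding categories."""
    rng = np.random.default_rng(spec.seed)
    records: list[PulldownRecord] = []
    rows = []

    def add(pid: str, category: str, sense: np.ndarray, anti: np.ndarray, mass: float) -> None:
        records.append(PulldownRecord(pid, mass, tuple(map(int, sense)), tuple(map(int, anti))))
        rows.append({"protein_id": pid, "true_category": category})

    for i in range(spec.n_unique):
        add(
            f"UNIQ{i:03d}",
            "unique",
            _truncated_poisson(rng, spec.base_mean, 3),
            np.zeros(3, int),
            50 + 10 * rng.random(),
        )
    for i in range(spec.n_enriched):
        add(
            f"ENRC{i:03d}",
            "enriched",
            rng.poisson(spec.enrichment_factor * spec.base_mean, 3),
            rng.poisson(spec.base_mean, 3),
            50 + 10 * rng.random(),
        )
    for i in range(spec.n_background):
        add(
            f"BACK{i:03d}",
            "background",
            rng.poisson(spec.base_mean, 3),
            rng.poisson(spec.base_mean, 3),
            50 + 10 * rng.random(),
        )
    proteins = pd.DataFrame(rows).set_index("protein_id")
    table = pd.DataFrame(
        [
            {"protein_id": r.protein_id, "s": r.sense_counts, "a": r.antisense_counts}
            for r in records
        ]
    )
    return records, SimTruth(proteins=proteins, checksum=_checksum_frame(table))


# ---------------------------------------------------------------------------
# RNA-seq counts


def _design_frame(spec: RnaSeqSimSpec) -> pd.DataFrame:
    rows = []
    layout = [("KD", ["control", *KD_LINES, STAT1_LINE]), ("OE", ["control", OE_LINE])]
    for experiment, lines in layout:
        for line in lines:
            for dose in ("mock", "low", "high"):
                for rep in range(1, spec.replicates + 1):
                    rows.append(
                        {
                            "sample_id": f"{experiment}_{line}_{dose}_r{rep}",
                            "experiment": experiment,
                            "perturbation": line,
                            "dose": dose,
                            "replicate": rep,
                        }
                    )
    return pd.DataFrame(rows)


def simulate_counts(spec: RnaSeqSimSpec) -> tuple[CountMatrix, SampleDesign, SimTruth]:
    """Simulate the factorial negative-binomial count matrix with planted truth."""
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:05d}" for i in range(spec.n_genes)]
    design = _design_frame(spec)

    is_isg = np.zeros(spec.n_genes, bool)
    is_isg[: spec.n_isg] = True
    is_core = np.zeros(spec.n_genes, bool)
    is_core[: spec.n_core] = True
    kd_only = np.zeros(spec.n_genes, bool)
    kd_only[spec.n_core : spec.n_core + spec.n_kd_only] = True
    oe_only = np.zeros(spec.n_genes, bool)
    oe_only[spec.n_core + spec.n_kd_only : spec.n_core + spec.n_kd_only + spec.n_oe_only] = True
    affected_kd = is_core | kd_only
    affected_oe = is_core | oe_only

    baseline = rng.normal(spec.baseline_log2_mean, spec.baseline_log2_sd, spec.n_genes)
    # planted ISGs are robustly expressed genes: anything at the detection
    # floor could never pass the read filter or show a quantifiable response
    baseline[is_isg] = rng.normal(
        spec.isg_baseline_log2_mean, spec.isg_baseline_log2_sd, int(is_isg.sum())
    )
    lo, hi = spec.isg_log2fc_range
    draws = np.sort(rng.uniform(lo, hi, (spec.n_genes, 2)), axis=1)
    resp_low = np.where(is_isg, draws[:, 0], 0.0)
    resp_high = np.where(is_isg, draws[:, 1], 0.0)

    # true response log2FC per (line, dose): start from the control response,
    # then modulate perturbed lines
    lines = ["control", *KD_LINES, STAT1_LINE, OE_LINE]
    true_resp: dict[tuple[str, str], np.ndarray] = {}
    for dose, ctrl_resp in (("low", resp_low), ("high", resp_high)):
        for line in lines:
            r = ctrl_resp.copy()
            if line in KD_LINES:
                r = r - np.where(affected_kd, spec.perturbation_delta, 0.0)
            elif line == OE_LINE:
                r = r + np.where(affected_oe, spec.perturbation_delta, 0.0)
            elif line == STAT1_LINE:
                r = r * np.where(is_isg, spec.stat1_attenuation, 1.0)
            true_resp[(line, dose)] = r

    libsize = np.exp(
        rng.uniform(np.log(spec.libsize_range[0]), np.log(spec.libsize_range[1]), len(design))
    )
    counts = np.empty((spec.n_genes, len(design)), dtype=np.int64)
    r_shape = 1.0 / spec.dispersion
    for j, row in enumerate(design.itertuples(index=False)):
        log2_mu = baseline.copy()
        if row.dose != "mock":
            log2_mu = log2_mu + true_resp[(row.perturbation, row.dose)]
        mu = libsize[j] * np.exp2(log2_mu)
        p = r_shape / (r_shape + mu)
        counts[:, j] = rng.negative_binomial(r_shape, p)

    matrix = CountMatrix(pd.DataFrame(counts, index=genes, columns=design["sample_id"].to_numpy()))
    gene_truth = pd.DataFrame(
        {
            "is_isg": is_isg,
            "is_core": is_core,
            "affected_in_KD": affected_kd,
            "affected_in_OE": affected_oe,
            "baseline_log2": baseline,
            "resp_low_control": resp_low,
            "resp_high_control": resp_high,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    responses = pd.DataFrame(
        {f"{line}:{dose}": v for (line, dose), v in true_resp.items()},
        index=pd.Index(genes, name="gene_id"),
    )
    truth = SimTruth(
        genes=gene_truth, responses=responses, checksum=_checksum_frame(matrix.counts)
    )
    return matrix, SampleDesign(design), truth


def write_simulation(
    matrix: CountMatrix, design: SampleDesign, truth: SimTruth, outdir: str | Path
) -> None:
    """Emit the counts TSV, design CSV (with ng/mL dose labels) and truth JSON."""
    from .counts import DOSE_LABELS, write_counts

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_counts(matrix, outdir / "counts.tsv")
    sheet = design.table.assign(dose=design.table["dose"].map(DOSE_LABELS))
    sheet.to_csv(outdir / "design.csv", index=False)
    truth.to_json(outdir / "truth.json")
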