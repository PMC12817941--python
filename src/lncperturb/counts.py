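"""Count-matrix loading, expression filtering and TMM normalization.

The pipeline starts from a gene x sample matrix of read counts and a sample
design sheet describing the factorial layout: two experiments (knockdown and
overexpression), each with a control cell line and one or more perturbed
lines, treated with mock or one of two interferon-beta doses in triplicate.

Normalization is the trimmed mean of M-values (TMM): each sample is compared
with a reference sample on the log-ratio (M) / log-abundance (A) plane, the
extreme 30% of M-values and 5% of A-values are trimmed, and the scaling
factor is the precision-weighted mean of the surviving M-values.  Factors
are rescaled to geometric mean one, and expression is reported as log2
counts per million over the effective (factor-adjusted) library size with a
library-size-proportional pseudo-count.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "CountMatrix",
    "SampleDesign",
    "NormalizedExpression",
    "filter_genes",
    "tmm_factors",
    "log_cpm",
    "normalize",
    "read_counts",
    "read_design",
    "write_counts",
]

logger = logging.getLogger(__name__)

DOSES = ("mock", "low", "high")
#: Design-sheet vocabulary for the two interferon-beta doses.
DOSE_LABELS = {"mock": "mock", "low": "1 ng/mL", "high": "10 ng/mL"}
_LABEL_TO_DOSE = {v: k for k, v in DOSE_LABELS.items()}


class DesignError(ValueError):
    """Inconsistent count matrix / design sheet configuration."""


@dataclass(frozen=True)
class CountMatrix:
    """Integer read counts, genes in rows, samples in columns."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.duplicated().any():
            raise DesignError("duplicate gene ids")
        if df.columns.duplicated().any():
            raise DesignError("duplicate sample ids")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise DesignError("counts must be integers")
            object.__setattr__(self, "counts", df.astype(np.int64))
        if (self.counts.to_numpy() < 0).any():
            raise DesignError("negative counts")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class SampleDesign:
    """Per-sample factorial metadata.

    ``table`` columns: sample_id, experiment (KD/OE), perturbation (control
    or a perturbed-line id), dose (mock/low/high), replicate.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "experiment", "perturbation", "dose", "replicate")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise DesignError(f"design sheet missing column(s) {missing}")
        if t["sample_id"].duplicated().any():
            raise DesignError("duplicate sample_id in design sheet")
        doses = t["dose"].map(lambda d: _LABEL_TO_DOSE.get(d, d))
        bad = sorted(set(doses) - set(DOSES))
        if bad:
            raise DesignError(f"unknown dose label(s) {bad}; expected {DOSES} or ng/mL labels")
        if not doses.equals(t["dose"]):
            t = t.assign(dose=doses)
            object.__setattr__(self, "table", t)

    def for_samples(self, sample_ids) -> "SampleDesign":
        t = self.table.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return SampleDesign(t)

    def experiments(self) -> list[str]:
        return sorted(self.table["experiment"].unique())

    def check_against(self, m: CountMatrix) -> None:
        design_ids = set(self.table["sample_id"])
        matrix_ids = set(m.sample_ids)
        if design_ids != matrix_ids:
            raise DesignError(
                f"design/matrix sample mismatch: only in design {sorted(design_ids - matrix_ids)}, "
                f"only in matrix {sorted(matrix_ids - design_ids)}"
            )

    def min_cell_replication(self) -> int:
        cells = self.table.groupby(["experiment", "perturbation", "dose"]).size()
        return int(cells.min())


@dataclass(frozen=True)
class NormalizedExpression:
    """log2 CPM expression with the normalization that produced it."""

    log_cpm: pd.DataFrame
    norm_factors: pd.Series
    library_sizes: pd.Series
    prior_count: float

    def __post_init__(self) -> None:
        f = self.norm_factors.to_numpy(float)
        if (f <= 0).any():
            raise DesignError("normalization factors must be positive")
        if abs(float(np.mean(np.log(f)))) > 1e-12:
            raise DesignError("normalization factors must have geometric mean 1")
        if not np.isfinite(self.log_cpm.to_numpy()).all():
            raise DesignError("non-finite log2 CPM")


# ---------------------------------------------------------------------------
# Filtering


def filter_genes(
    m: CountMatrix,
    d: SampleDesign,
    min_count: int = 30,
    min_samples: int = 3,
    across_experiments: str = "any",
) -> CountMatrix:
    """Remove weakly covered genes.

    Within each experiment a gene is kept when it has at least ``min_count``
    reads in at least ``min_samples`` samples of the perturbation group (all
    perturbed-line samples, any dose) or of the control group.  With both
    experiments present the rule is evaluated per experiment and combined
    with ``across_experiments`` ('any' keeps a gene passing in either
    experiment, 'all' requires both).  Input gene order is preserved.
    """
    d.check_against(m)
    if across_experiments not in ("any", "all"):
        raise DesignError("across_experiments must be 'any' or 'all'")
    per_experiment = []
    for exp in d.experiments():
        sub = d.table[d.table["experiment"] == exp]
        ctrl = sub.loc[sub["perturbation"] == "control", "sample_id"]
        pert = sub.loc[sub["perturbation"] != "control", "sample_id"]
        if ctrl.empty or pert.empty:
            raise DesignError(f"experiment {exp!r} lacks a control or perturbation group")
        keep = pd.Series(False, index=m.counts.index)
        for group in (pert, ctrl):
            hits = (m.counts[list(group)] >= min_count).sum(axis=1)
            keep |= hits >= min_samples
        per_experiment.append(keep)
    combined = pd.concat(per_experiment, axis=1)
    keep = combined.any(axis=1) if across_experiments == "any" else combined.all(axis=1)
    logger.info(
        "gene filter (>=%d reads in >=%d samples, per experiment, combined with %r): "
        "%d of %d genes retained",
        min_count, min_samples, across_experiments, int(keep.sum()), len(keep),
    )
    return CountMatrix(m.counts.loc[keep])


# ---------------------------------------------------------------------------
# TMM


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
    trim_m: float, trim_a: float,
) -> float:
    """TMM scaling factor of one sample against the reference (log2 scale -> 2**)."""
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        raise DesignError("sample shares no positive genes with the TMM reference")
    o = obs[pos].astype(float)
    r = ref[pos].astype(float)
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    v = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m, hi_m = math.floor(n * trim_m) + 1, n + 1 - (math.floor(n * trim_m) + 1)
    lo_a, hi_a = math.floor(n * trim_a) + 1, n + 1 - (math.floor(n * trim_a) + 1)
    rm, ra = rankdata(m), rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_factors(m: CountMatrix, trim_m: float = 0.3, trim_a: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, geometric mean one.

    The reference sample is the one whose upper-quartile count rate is
    closest to the mean upper quartile across samples.  Per sample, the
    doubly trimmed (``trim_m`` on M, ``trim_a`` on A), inverse-variance
    weighted mean M against the reference gives the log2 factor.
    """
    counts = m.counts.to_numpy(float)
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise DesignError("every sample must have library size > 0")
    uq = np.array([np.quantile(counts[:, j] / lib[j], 0.75) for j in range(counts.shape[1])])
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    ref = counts[:, ref_idx]
    factors = np.array(
        [
            _tmm_pair(counts[:, j], ref, lib[j], lib[ref_idx], trim_m, trim_a)
            for j in range(counts.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=m.sample_ids, name="norm_factor")


def log_cpm(m: CountMatrix, factors: pd.Series, prior_count: float = 3.0) -> NormalizedExpression:
    """log2 counts-per-million over effective library sizes.

    The pseudo-count is scaled per sample proportionally to its effective
    library size (``prior * L_s / mean(L)``), so a zero count maps to the
    same CPM floor in every sample:

        log2( (count + prior_s) / (L_s + 2 * prior_s) * 1e6 )
    """
    if prior_count <= 0:
        raise DesignError("prior_count must be positive")
    factors = factors.reindex(m.sample_ids)
    lib = m.library_sizes.to_numpy(float)
    eff = lib * factors.to_numpy(float)
    prior = prior_count * eff / eff.mean()
    vals = np.log2((m.counts.to_numpy(float) + prior[None, :]) / (eff + 2 * prior)[None, :] * 1e6)
    df = pd.DataFrame(vals, index=m.gene_ids, columns=m.sample_ids)
    return NormalizedExpression(df, factors, m.library_sizes.astype(float), prior_count)


def normalize(
    m: CountMatrix,
    d: SampleDesign,
    min_count: int = 30,
    min_samples: int = 3,
    prior_count: float = 3.0,
) -> NormalizedExpression:
    """Filter + TMM + log-CPM in one call (the standard preprocessing chain)."""
    filtered = filter_genes(m, d, min_count=min_count, min_samples=min_samples)
    return log_cpm(filtered, tmm_factors(filtered), prior_count=prior_count)


# ---------------------------------------------------------------------------
# I/O


def read_counts(path: str | Path) -> CountMatrix:
    """Read a TSV count matrix: first column gene_id, one column per sample."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.astype(str)
    return CountMatrix(df)


def write_counts(m: CountMatrix, path: str | Path) -> None:
    m.counts.rename_axis("gene_id").to_csv(path, sep="\t")


def read_design(path: str | Path) -> SampleDesign:
    """Read a design sheet CSV (sample_id, experiment, perturbation, dose, replicate)."""
    return SampleDesign(pd.read_csv(path, comment="#", dtype={"sample_id": str}))
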