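"""Inter/intra-laboratory consistency analysis of slide-level scar scores.

With four stain sets (two laboratories x two batches) every method yields
six unordered stain-set pairs — two intra-laboratory, four inter-laboratory.
Consistency of a method is the Spearman rank correlation of its per-case
scores across each pair; a method robust to staining variation keeps the
case ranking and scores rho near 1.  Grouping summaries are reported both
as the median of per-pair rho and as the pooled-observations rho, since a
single printed summary can be either.  Stain-based scores are additionally
correlated against a stain-free reference (the SHG analogue) on one set.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

SCORE_COLUMNS = ["case_id", "stain_set", "method", "psr_percent"]


class UndefinedCorrelationError(ValueError):
    """Spearman rho undefined (zero rank variance or too few pairs)."""


@dataclass(frozen=True)
class PairCorrelation:
    """Spearman rho of one stain-set pair for one method."""

    pair: tuple[str, str]
    pair_type: str  # "intra" | "inter"
    rho: float | None
    n: int

    def __post_init__(self) -> None:
        if self.pair_type not in ("intra", "inter"):
            raise ValueError("pair_type must be intra or inter")
        if self.rho is not None and not -1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12:
            raise ValueError("|rho| must be <= 1")


@dataclass
class MethodConsistency:
    """All pair correlations and grouping summaries for one method."""

    method: str
    pairs: list[PairCorrelation]
    median_intra: float | None
    median_inter: float | None
    median_all: float | None
    pooled_intra: float | None
    pooled_inter: float | None
    pooled_all: float | None


@dataclass
class ConsistencyReport:
    methods: dict[str, MethodConsistency] = field(default_factory=dict)
    reference_correlations: dict[str, float | None] = field(default_factory=dict)
    reference_method: str = ""
    reference_stain_set: str = ""


def build_stain_pairs(
    set_labels: Sequence[str],
    laboratory_of: Mapping[str, str],
) -> list[tuple[tuple[str, str], str]]:
    """All unordered stain-set pairs, typed intra/inter-laboratory.

    For the four-set design {E1, E2, N1, N2} this yields six pairs, two
    intra and four inter.
    """
    labels = list(set_labels)
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate stain-set labels")
    if len(labels) < 2:
        raise ValueError("need at least two stain sets")
    missing = [s for s in labels if s not in laboratory_of]
    if missing:
        raise ValueError(f"laboratory mapping missing sets: {missing}")
    out = []
    for a, b in itertools.combinations(labels, 2):
        kind = "intra" if laboratory_of[a] == laboratory_of[b] else "inter"
        out.append(((a, b), kind))
    return out


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks.

    Pairs with a missing value on either side are dropped (logged).  Raises
    :class:`UndefinedCorrelationError` when fewer than 3 complete pairs
    remain or either vector has zero rank variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    dropped = int((~keep).sum())
    if dropped:
        logger.info("spearman_rho: dropped %d incomplete pairs", dropped)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise UndefinedCorrelationError("fewer than 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero rank variance")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = sps.spearmanr(x, y).statistic
    if np.isnan(rho):
        raise UndefinedCorrelationError("correlation undefined")
    return float(rho)


def _safe_rho(x, y) -> tuple[float | None, int]:
    n = int(np.count_nonzero(~(np.isnan(np.asarray(x, float)) | np.isnan(np.asarray(y, float)))))
    try:
        return spearman_rho(x, y), n
    except UndefinedCorrelationError:
        return None, n


def _median(values: list[float | None]) -> float | None:
    vals = [v for v in values if v is not None]
    return float(np.median(vals)) if vals else None


def method_consistency(
    scores: pd.DataFrame,
    method: str,
    pairs: Sequence[tuple[tuple[str, str], str]],
) -> MethodConsistency:
    """Per-pair Spearman rho plus median and pooled grouping summaries.

    Pooled summaries concatenate the per-case observations of every pair in
    the grouping before computing one rho; undefined pair correlations are
    reported as missing, never coerced to 0.
    """
    sub = scores[scores["method"] == method]
    wide = sub.pivot_table(index="case_id", columns="stain_set", values="psr_percent")
    pair_results: list[PairCorrelation] = []
    pooled: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {"intra": [], "inter": []}
    for (a, b), kind in pairs:
        if a not in wide.columns or b not in wide.columns:
            pair_results.append(PairCorrelation((a, b), kind, None, 0))
            continue
        rho, n = _safe_rho(wide[a].to_numpy(), wide[b].to_numpy())
        pair_results.append(PairCorrelation((a, b), kind, rho, n))
        pooled[kind].append((wide[a].to_numpy(), wide[b].to_numpy()))

    def pooled_rho(kinds: Sequence[str]) -> float | None:
        xs = [x for k in kinds for x, _ in pooled[k]]
        ys = [y for k in kinds for _, y in pooled[k]]
        if not xs:
            return None
        rho, _ = _safe_rho(np.concatenate(xs), np.concatenate(ys))
        return rho

    return MethodConsistency(
        method=method,
        pairs=pair_results,
        median_intra=_median([p.rho for p in pair_results if p.pair_type == "intra"]),
        median_inter=_median([p.rho for p in pair_results if p.pair_type == "inter"]),
        median_all=_median([p.rho for p in pair_results]),
        pooled_intra=pooled_rho(["intra"]),
        pooled_inter=pooled_rho(["inter"]),
        pooled_all=pooled_rho(["intra", "inter"]),
    )


def reference_correlation(
    scores: pd.DataFrame,
    method: str,
    reference_method: str,
    stain_set: str,
) -> float:
    """Spearman rho between a method's scores on one set and a stain-free reference.

    The reference is stain-set independent: its values are taken from any
    set present (it is stored once per case).
    """
    m = scores[(scores["method"] == method) & (scores["stain_set"] == stain_set)]
    r = scores[scores["method"] == reference_method]
    ref_per_case = r.groupby("case_id")["psr_percent"].first()
    merged = m.set_index("case_id")["psr_percent"].to_frame("score").join(
        ref_per_case.to_frame("ref"), how="inner"
    )
    return spearman_rho(merged["score"].to_numpy(), merged["ref"].to_numpy())


# ---------------------------------------------------------------------------
# score-table I/O

def read_score_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a slide-score table (CSV or XLSX).

    Columns: case_id, stain_set, method, psr_percent.  Rejects duplicate
    (case, set, method) keys and out-of-range percentages.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        table = pd.read_excel(path)
    else:
        table = pd.read_csv(path)
    missing = [c for c in SCORE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"score table missing columns: {missing}")
    table = table[SCORE_COLUMNS].copy()
    table["case_id"] = table["case_id"].astype(str)
    table["stain_set"] = table["stain_set"].astype(str)
    table["method"] = table["method"].astype(str)
    table["psr_percent"] = table["psr_percent"].astype(float)
    dup = table.duplicated(subset=["case_id", "stain_set", "method"], keep=False)
    if dup.any():
        rows = table[dup].index.tolist()
        raise ValueError(f"duplicate (case, stain_set, method) rows: {rows}")
    bad = ~table["psr_percent"].between(0.0, 100.0)
    if bad.any():
        raise ValueError(f"psr_percent outside [0, 100] at rows: {table[bad].index.tolist()}")
    return table


def write_score_table(table: pd.DataFrame, path: str | Path) -> None:
    table[SCORE_COLUMNS].to_csv(path, index=False)


def report_frames(report: ConsistencyReport) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format pair table and per-method summary table."""
    pair_rows = [
        {
            "method": name,
            "pair": f"{p.pair[0]}-{p.pair[1]}",
            "pair_type": p.pair_type,
            "rho": p.rho,
            "n": p.n,
        }
        for name, mc in report.methods.items()
        for p in mc.pairs
    ]
    summary_rows = [
        {
            "method": name,
            "median_intra": mc.median_intra,
            "median_inter": mc.median_inter,
            "median_all": mc.median_all,
            "pooled_intra": mc.pooled_intra,
            "pooled_inter": mc.pooled_inter,
            "pooled_all": mc.pooled_all,
            "reference_rho": report.reference_correlations.get(name),
        }
        for name, mc in report.methods.items()
    ]
    return pd.DataFrame(pair_rows), pd.DataFrame(summary_rows)


def write_report(report: ConsistencyReport, out_dir: str | Path) -> tuple[Path, Path]:
    """Emit the pairs CSV and the summary CSV; returns their paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pairs, summary = report_frames(report)
    pairs_path = out / "pair_correlations.csv"
    summary_path = out / "method_summary.csv"
    pairs.to_csv(pairs_path, index=False)
    summary.to_csv(summary_path, index=False)
    return pairs_path, summary_path
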