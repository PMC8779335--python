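"""Orchestration: run the full evaluation and emit table/figure analogues.

``run_evaluation`` binds the per-pair operations (similarity, library rank,
peak concordance, molecular-ion comparison, neutral-loss annotation) into
one per-compound record table plus the aggregate summaries: score
histograms, per-subclass band tables, top-N identification counts and
per-subclass molecular-ion accuracy.  Aggregates are pure functions of the
records, so recomputing them from the record table reproduces them exactly.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import concordance as conc
from . import molion, neutral_loss, search, similarity
from .spectral_io import Spectrum, SpectrumLibrary

__all__ = [
    "EvalConfig",
    "EvaluationReport",
    "run_evaluation",
    "score_histogram",
    "subclass_band_table",
    "plot_similarity_heatmap",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvalConfig:
    """Knobs of one evaluation run (echoed into every tabular output)."""

    weights: similarity.SimilarityWeights = similarity.DEFAULT_WEIGHTS
    banding_scheme: str = "fig_bands"
    concordance_thresholds: tuple[float, ...] = (2.0, 20.0)
    molion_window_pct: float = 2.0
    search_depth: int = 100
    metric: str = "wdot"
    min_loss_intensity: float = 2.0
    max_loss_generation: int = 2

    def to_yaml(self) -> str:
        w = self.weights
        return yaml.safe_dump(
            {
                "weights": {
                    "intensity_exponent": w.intensity_exponent,
                    "mass_exponent": w.mass_exponent,
                    "scale_a": w.scale_a,
                },
                "banding_scheme": self.banding_scheme,
                "concordance_thresholds": list(self.concordance_thresholds),
                "molion_window_pct": self.molion_window_pct,
                "search_depth": self.search_depth,
                "metric": self.metric,
                "min_loss_intensity": self.min_loss_intensity,
                "max_loss_generation": self.max_loss_generation,
            },
            sort_keys=False,
        )


@dataclass
class EvaluationReport:
    """Per-compound records plus aggregate tables for one evaluation run."""

    records: pd.DataFrame
    topn: search.TopNSummary
    molion_summary: list[molion.ClassSummary]
    loss_hits: dict[str, list[neutral_loss.NeutralLossHit]]
    config: EvalConfig

    @property
    def mean_wdot(self) -> float:
        return float(self.records["wdot"].mean())

    def to_tsv(self) -> str:
        front = "\n".join("# " + line for line in self.config.to_yaml().splitlines())
        return front + "\n" + self.records.to_csv(sep="\t", index=False)


def run_evaluation(
    predicted: SpectrumLibrary,
    experimental: SpectrumLibrary,
    search_library: SpectrumLibrary | None = None,
    config: EvalConfig = EvalConfig(),
) -> EvaluationReport:
    """Evaluate every predicted/experimental pair (matched by spectrum id).

    ``search_library`` (defaults to ``experimental``) must contain every
    experimental entry; unpaired ids raise with the offending list.
    Deterministic given inputs and config.
    """
    pred_ids = set(predicted.ids())
    exp_ids = set(experimental.ids())
    unpaired = sorted(pred_ids ^ exp_ids)
    if unpaired or not pred_ids:
        raise ValueError(f"unpaired spectrum ids: {unpaired or 'no pairs at all'}")
    search_library = search_library or experimental

    t0 = time.perf_counter()
    rows = []
    loss_hits: dict[str, list[neutral_loss.NeutralLossHit]] = {}
    ranks: list[search.RankResult] = []
    for exp in experimental:
        pred = predicted[exp.id]
        score = similarity.score_pair(pred, exp, config.weights, config.banding_scheme)
        rank = search.rank_query(
            pred, search_library, exp.id, config.metric, config.weights, config.search_depth
        )
        ranks.append(rank)
        mc = molion.compare_molecular_ions(pred, exp)
        hits = neutral_loss.detect_neutral_losses(
            pred,
            min_intensity=config.min_loss_intensity,
            max_generation=config.max_loss_generation,
        )
        loss_hits[exp.id] = hits
        row = {
            "id": exp.id,
            "subclass": exp.subclass,
            "cosine": score.cosine,
            "wdot": score.wdot,
            "band": score.band,
            "rank": rank.rank,
            "molion_exp": mc.exp_abundance,
            "molion_pred": mc.pred_abundance,
            "molion_diff": mc.signed_diff,
            "molion_class": molion.classify_prediction(mc, config.molion_window_pct),
            "n_loss_hits": len(hits),
        }
        for t in config.concordance_thresholds:
            r = conc.concordance(pred, exp, t)
            row[f"pct_matched_{t:g}"] = r.pct_matched
            row[f"jaccard_{t:g}"] = r.jaccard
            row[f"extra_{t:g}"] = r.extra
        rows.append(row)
    records = pd.DataFrame(rows)

    comparisons = [
        molion.compare_molecular_ions(predicted[e.id], e) for e in experimental
    ]
    report = EvaluationReport(
        records=records,
        topn=search.topn_summary(ranks, wdot_scores=list(records["wdot"])),
        molion_summary=molion.class_summary(comparisons, config.molion_window_pct),
        loss_hits=loss_hits,
        config=config,
    )
    log.info(
        "evaluated %d pairs against %d library entries in %.2f s",
        len(records), len(search_library), time.perf_counter() - t0,
    )
    return report


def score_histogram(
    report: EvaluationReport | pd.DataFrame, metric: str = "wdot", bin_width: int = 100
) -> pd.Series:
    """Binned score counts over 0-1000; bins ``[low, low+width)``, top bin closed.

    Counts sum to the number of records.
    """
    records = report.records if isinstance(report, EvaluationReport) else report
    if len(records) == 0:
        raise ValueError("no records to histogram")
    scores = records[metric].to_numpy()
    n_bins = int(np.ceil(1000 / bin_width))
    idx = np.minimum((scores // bin_width).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    edges = [int(i * bin_width) for i in range(n_bins)]
    return pd.Series(counts, index=edges, name=metric)


def subclass_band_table(report: EvaluationReport, metric: str = "wdot") -> pd.DataFrame:
    """Per-subclass mean score (integer display) and counts per quality band."""
    records = report.records
    if "subclass" not in records:
        raise ValueError("records carry no subclass labels")
    bands = [label for _, label in similarity.BANDING_SCHEMES[report.config.banding_scheme]]
    rows = []
    for subclass, grp in records.groupby("subclass", sort=False):
        row = {"subclass": subclass, "n": len(grp), "mean": round(float(grp[metric].mean()))}
        for b in bands:
            row[b] = int((grp["band"] == b).sum())
        rows.append(row)
    return pd.DataFrame(rows)


def plot_similarity_heatmap(matrix: pd.DataFrame, path: str, title: str = "") -> None:
    """Write a pairwise-score heatmap image (static export only)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(matrix.to_numpy(), cmap="RdYlBu", vmin=0, vmax=1000)
    ax.set_title(title or "pairwise similarity")
    ax.set_xlabel("library entry")
    ax.set_ylabel("query")
    fig.colorbar(im, ax=ax, label="score")
    fig.savefig(path, dpi=150)
    plt.close(fig)
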