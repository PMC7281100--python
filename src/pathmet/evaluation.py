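"""Scoring against ground truth and annotation-comparison scenario labels.

AUC follows the Mann-Whitney convention (ties get half credit), precision /
recall / accuracy use inclusive thresholding (posterior >= threshold calls a
pathway active), and the benchmark harness regenerates synthetic datasets on
a fraction grid, scoring the sampler posterior against the enrichment-ratio
baseline replicate by replicate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .exceptions import InputError
from .model import MetabolicModel, Parameters
from .inference import gibbs_sample_posterior
from .enrichment import enrichment_ratio
from .synthetic import generate_synthetic_dataset

__all__ = [
    "roc_auc",
    "classification_metrics",
    "ClassificationMetrics",
    "compare_candidate_sets",
    "BenchmarkGrid",
    "BenchmarkReport",
    "run_benchmark",
]

#: Default fraction grid: pathway-activity fractions x metabolite fractions.
DEFAULT_FRAC_PATHWAYS = (0.3, 0.5, 0.7)
DEFAULT_FRAC_METABOLITES = (0.05, 0.10, 0.15, 0.20, 0.25, 0.50, 0.75)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve; equals P(score_active > score_inactive) + tie/2.

    Returns NaN (with a warning) when only one class is present, where the
    ranking probability is undefined.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise InputError("scores and labels must have the same length")
    if len(np.unique(labels)) < 2:
        warnings.warn(
            "AUC is undefined with a single ground-truth class; returning NaN",
            stacklevel=2,
        )
        return float("nan")
    return float(roc_auc_score(labels, scores))


@dataclass
class ClassificationMetrics:
    precision: float  # NaN when no pathway is called active
    recall: float
    accuracy: float
    tp: int
    fp: int
    fn: int
    tn: int


def classification_metrics(
    posteriors, threshold: float, true_a
) -> ClassificationMetrics:
    """Precision / recall / accuracy of activity calls at a posterior cutoff.

    A pathway is called active when its posterior is >= ``threshold``
    (inclusive).  Precision with no positive calls is reported as NaN rather
    than imputed.
    """
    post = np.asarray(posteriors, dtype=float)
    truth = np.asarray(true_a).astype(bool)
    if post.shape != truth.shape:
        raise InputError("posteriors and true_a must have the same length")
    called = post >= threshold
    tp = int((called & truth).sum())
    fp = int((called & ~truth).sum())
    fn = int((~called & truth).sum())
    tn = int((~called & ~truth).sum())
    precision = tp / (tp + fp) if (tp + fp) else float("nan")
    recall = tp / (tp + fn) if (tp + fn) else float("nan")
    accuracy = (tp + tn) / truth.size
    return ClassificationMetrics(precision, recall, accuracy, tp, fp, fn, tn)


def compare_candidate_sets(
    top_set: set,
    reference: set,
    reference_is_isomer: bool = False,
    reference_in_model: bool = True,
) -> str:
    """Classify how a top-ranked annotation set relates to a reference set.

    Tool-vs-tool mode (default flags) labels "agreement" (sets equal),
    "semi_agreement" (reference a proper subset of the top set),
    "disagreement" (nonempty reference sharing nothing -- or overlapping
    without either containment, which is classified as disagreement too) and
    "only_model" (empty reference: only this method annotated the mass).
    With ``reference_in_model=False`` the reference compound is missing from
    the metabolic model ("model_incompleteness"); with
    ``reference_is_isomer=True`` a reference isomer class containing a
    top-set member is a "clarification" -- the posterior ranking resolved an
    isomer-level annotation to a specific compound.
    """
    if not reference:
        return "only_model"
    if not reference_in_model:
        return "model_incompleteness"
    if reference_is_isomer:
        return "clarification" if reference & top_set else "disagreement"
    if reference == top_set:
        return "agreement"
    if reference < top_set:
        return "semi_agreement"
    if reference & top_set:
        warnings.warn(
            "candidate sets overlap without containment; classified as "
            "disagreement",
            stacklevel=2,
        )
    return "disagreement"


@dataclass
class BenchmarkGrid:
    """Configuration of the synthetic validation sweep."""

    frac_pathways: tuple = DEFAULT_FRAC_PATHWAYS
    frac_metabolites: tuple = DEFAULT_FRAC_METABOLITES
    n_replicates: int = 10
    gamma: float = 1.0


@dataclass
class BenchmarkReport:
    """Per-replicate scores and their aggregates."""

    rows: pd.DataFrame
    config: dict = field(default_factory=dict)

    def aggregate(self) -> pd.DataFrame:
        """Mean scores per grid cell (NaN precision/AUC rows excluded per metric)."""
        return (
            self.rows.groupby(["frac_pathways", "frac_metabolites"], as_index=False)[
                ["auc_posterior", "auc_enrichment", "precision", "recall", "accuracy"]
            ].mean()
        )

    def overall(self) -> dict:
        cols = ["auc_posterior", "auc_enrichment", "precision", "recall", "accuracy"]
        out = {c: float(self.rows[c].mean()) for c in cols}
        out["n_rows"] = int(len(self.rows))
        out["n_undefined_precision"] = int(self.rows["precision"].isna().sum())
        out["n_single_class"] = int(self.rows["auc_posterior"].isna().sum())
        return out


def run_benchmark(
    model: MetabolicModel,
    grid: BenchmarkGrid | None = None,
    params: Parameters | None = None,
    seed: int | None = None,
) -> BenchmarkReport:
    """Synthetic validation sweep: posterior inference vs the enrichment ratio.

    For every (pathway fraction, metabolite fraction, replicate) cell a
    dataset is generated, the Gibbs posterior and the enrichment ratios are
    computed, and both score vectors are evaluated against the ground-truth
    activities (AUC; precision/recall/accuracy at the activity threshold for
    the posterior).  Each row records the derived seed that reproduces it.
    """
    grid = grid or BenchmarkGrid()
    params = params or Parameters(gamma=grid.gamma)
    if params.gamma != grid.gamma:
        params = Parameters(**{**params.__dict__, "gamma": grid.gamma})
    ss = np.random.SeedSequence(seed)
    records = []
    for fp in grid.frac_pathways:
        for fm in grid.frac_metabolites:
            for rep in range(grid.n_replicates):
                (child,) = ss.spawn(1)
                cell_seed = int(child.generate_state(1, np.uint32)[0])
                try:
                    rec = _benchmark_cell(model, fp, fm, rep, cell_seed, grid, params)
                except Exception as err:  # pragma: no cover - defensive
                    raise RuntimeError(
                        f"benchmark cell (frac_pathways={fp}, "
                        f"frac_metabolites={fm}, replicate={rep}) failed"
                    ) from err
                records.append(rec)
    rows = pd.DataFrame.from_records(records)
    return BenchmarkReport(
        rows=rows,
        config=dict(
            frac_pathways=list(grid.frac_pathways),
            frac_metabolites=list(grid.frac_metabolites),
            n_replicates=grid.n_replicates,
            gamma=grid.gamma,
            seed=seed,
        ),
    )


def _benchmark_cell(model, fp, fm, rep, cell_seed, grid, params) -> dict:
    rng = np.random.default_rng(cell_seed)
    data = generate_synthetic_dataset(model, fp, fm, grid.gamma, rng)
    samples = gibbs_sample_posterior(model, data.w, params, seed=cell_seed)
    ratios = np.array(
        [enrichment_ratio(model, data.w, i).ratio for i in range(model.n_pathways)]
    )
    single_class = len(np.unique(data.true_a)) < 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        auc_post = roc_auc(samples.pathway_posterior, data.true_a)
        auc_enr = roc_auc(ratios, data.true_a)
    m = classification_metrics(
        samples.pathway_posterior, params.activity_threshold, data.true_a
    )
    return dict(
        frac_pathways=fp,
        frac_metabolites=fm,
        replicate=rep,
        seed=cell_seed,
        single_class=single_class,
        auc_posterior=auc_post,
        auc_enrichment=auc_enr,
        precision=m.precision,
        recall=m.recall,
        accuracy=m.accuracy,
    )
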