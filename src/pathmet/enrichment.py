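"""Enrichment-ratio baseline with Fisher's Exact Test significance flags.

The enrichment ratio of a pathway is the fraction of its metabolites whose
mass bin was observed.  "Measured" is a metabolite-level notion: a shared bin
marks all of its candidate metabolites as putatively measured.  Statistical
enrichment is assessed with a one-sided (greater) Fisher's Exact Test on the
2x2 table of measured/unmeasured metabolites inside versus outside the
pathway, over all model metabolites; p <= 0.05 flags the pathway enriched.
No multiple-testing correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InputError
from .model import NO_BIN, MetabolicModel, ObservationVector

__all__ = [
    "EnrichmentResult",
    "measured_metabolites",
    "enrichment_ratio",
    "fisher_enrichment",
    "enrichment_table",
]

#: Raw significance cutoff for the enriched flag.
ALPHA = 0.05


@dataclass
class EnrichmentResult:
    pathway_id: str
    ratio: float
    n_measured: int
    n_total: int
    fisher_p: float | None = None
    enriched: bool | None = None


def measured_metabolites(
    model: MetabolicModel, w: np.ndarray | ObservationVector
) -> np.ndarray:
    """Boolean mask over metabolites whose mass bin is observed.

    Detached metabolites are never measured.
    """
    wv = w.w if isinstance(w, ObservationVector) else np.asarray(w)
    binof = model.bin_of_metabolite
    attached = binof != NO_BIN
    out = np.zeros(model.n_metabolites, dtype=bool)
    out[attached] = wv[binof[attached]] == 1
    return out


def enrichment_ratio(
    model: MetabolicModel, w: np.ndarray | ObservationVector, pathway: int
) -> EnrichmentResult:
    """Fraction of pathway metabolites in observed bins (the ratio baseline)."""
    if not 0 <= pathway < model.n_pathways:
        raise InputError(f"pathway index {pathway} out of range")
    members = model.membership[pathway].astype(bool)
    n_total = int(members.sum())
    if n_total == 0:
        raise InputError(
            f"pathway {model.pathway_ids[pathway]!r} has no metabolites; "
            "its enrichment ratio is undefined"
        )
    n_measured = int((measured_metabolites(model, w) & members).sum())
    return EnrichmentResult(
        pathway_id=model.pathway_ids[pathway],
        ratio=n_measured / n_total,
        n_measured=n_measured,
        n_total=n_total,
    )


def fisher_enrichment(
    model: MetabolicModel,
    w: np.ndarray | ObservationVector,
    pathway: int,
    alpha: float = ALPHA,
) -> EnrichmentResult:
    """Enrichment ratio plus a one-sided Fisher's Exact Test p-value.

    The 2x2 table counts [measured-in-pathway, unmeasured-in-pathway;
    measured-outside, unmeasured-outside] over the J model metabolites; the
    p-value is the exact hypergeometric upper tail.  A degenerate table
    (pathway spanning the whole model) yields p = 1 with a warning.
    """
    res = enrichment_ratio(model, w, pathway)
    members = model.membership[pathway].astype(bool)
    measured = measured_metabolites(model, w)
    inside_meas = res.n_measured
    inside_unmeas = res.n_total - inside_meas
    outside_meas = int((measured & ~members).sum())
    outside_unmeas = int((~measured & ~members).sum())
    if outside_meas + outside_unmeas == 0:
        warnings.warn(
            f"pathway {res.pathway_id!r} contains every model metabolite; "
            "enrichment against the rest of the model is undefined (p = 1)",
            stacklevel=2,
        )
        p = 1.0
    else:
        table = [[inside_meas, inside_unmeas], [outside_meas, outside_unmeas]]
        p = float(stats.fisher_exact(table, alternative="greater").pvalue)
    res.fisher_p = p
    res.enriched = p <= alpha
    return res


def enrichment_table(
    model: MetabolicModel,
    w: np.ndarray | ObservationVector,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Per-pathway enrichment ratios and Fisher flags as a data frame."""
    rows = [fisher_enrichment(model, w, i, alpha) for i in range(model.n_pathways)]
    return pd.DataFrame(
        {
            "pathway_id": [r.pathway_id for r in rows],
            "ratio": [r.ratio for r in rows],
            "n_measured": [r.n_measured for r in rows],
            "n_total": [r.n_total for r in rows],
            "fisher_p": [r.fisher_p for r in rows],
            "enriched": [r.enriched for r in rows],
        }
    )
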