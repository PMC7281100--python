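"""Tabular input/output.

Models arrive as two TSV files -- ``metabolites.tsv`` (metabolite_id, mass,
optional name) and ``membership.tsv`` (pathway_id, metabolite_id) -- or a
single JSON document with the same content.  Measurements are TSV with
columns ``mz`` and ``mode`` (positive / negative / neutral).  All outputs are
UTF-8 tab-separated tables with a header row and posteriors printed to six
decimal places.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InputError
from .model import (
    NO_BIN,
    MeasurementRecord,
    MetabolicModel,
    ObservationVector,
)
from .annotation import AnnotationResult
from .inference import PosteriorSamples

FLOAT_FMT = "%.6f"


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except Exception as err:
        raise InputError(f"cannot read {path}: {err}") from err
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required column(s) {missing}")
    return df


def _parse_float(df: pd.DataFrame, col: str, path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = np.flatnonzero(vals.isna().to_numpy())
    if bad.size:
        # +2: header line plus 1-based numbering
        raise InputError(
            f"{path}: non-numeric value in column {col!r} at line {bad[0] + 2}"
        )
    return vals.to_numpy(dtype=float)


def read_model_tsv(
    metabolites_path, membership_path, ppm_tol: float = 15.0
) -> MetabolicModel:
    """Build a model from metabolites.tsv + membership.tsv."""
    mets = _read_tsv(metabolites_path, ["metabolite_id", "mass"])
    masses = _parse_float(mets, "mass", metabolites_path)
    met_ids = mets["metabolite_id"].tolist()
    if len(set(met_ids)) != len(met_ids):
        raise InputError(f"{metabolites_path}: duplicate metabolite_id values")
    names = mets["name"].tolist() if "name" in mets.columns else None
    memb = _read_tsv(membership_path, ["pathway_id", "metabolite_id"])
    pathway_ids = list(dict.fromkeys(memb["pathway_id"]))
    met_index = {m: j for j, m in enumerate(met_ids)}
    pw_index = {p: i for i, p in enumerate(pathway_ids)}
    matrix = np.zeros((len(pathway_ids), len(met_ids)), dtype=np.uint8)
    for line, (pw, met) in enumerate(zip(memb["pathway_id"], memb["metabolite_id"]), start=2):
        if met not in met_index:
            raise InputError(
                f"{membership_path}: unknown metabolite_id {met!r} at line {line}"
            )
        matrix[pw_index[pw], met_index[met]] = 1
    return MetabolicModel.from_masses(
        pathway_ids=pathway_ids,
        metabolite_ids=met_ids,
        metabolite_mass=masses,
        membership=matrix,
        ppm_tol=ppm_tol,
        metabolite_names=names,
    )


def read_model_json(path, ppm_tol: float = 15.0) -> MetabolicModel:
    """Build a model from one JSON document.

    Expected keys: ``metabolites`` (list of {metabolite_id, mass, name?}) and
    ``pathways`` (mapping pathway_id -> list of metabolite ids).
    """
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    try:
        mets = doc["metabolites"]
        pathways = doc["pathways"]
        met_ids = [m["metabolite_id"] for m in mets]
        masses = [float(m["mass"]) for m in mets]
    except (KeyError, TypeError, ValueError) as err:
        raise InputError(f"{path}: malformed model document ({err})") from err
    met_index = {m: j for j, m in enumerate(met_ids)}
    matrix = np.zeros((len(pathways), len(met_ids)), dtype=np.uint8)
    for i, (pw, members) in enumerate(pathways.items()):
        for met in members:
            if met not in met_index:
                raise InputError(f"{path}: pathway {pw!r} lists unknown metabolite {met!r}")
            matrix[i, met_index[met]] = 1
    return MetabolicModel.from_masses(
        pathway_ids=list(pathways),
        metabolite_ids=met_ids,
        metabolite_mass=masses,
        membership=matrix,
        ppm_tol=ppm_tol,
        metabolite_names=[m.get("name") for m in mets] if any("name" in m for m in mets) else None,
    )


def write_model_tsv(model: MetabolicModel, metabolites_path, membership_path) -> None:
    pd.DataFrame(
        {
            "metabolite_id": model.metabolite_ids,
            "mass": model.metabolite_mass,
        }
    ).to_csv(metabolites_path, sep="\t", index=False, float_format="%.9f")
    rows = [
        (model.pathway_ids[i], model.metabolite_ids[j])
        for i in range(model.n_pathways)
        for j in np.flatnonzero(model.membership[i])
    ]
    pd.DataFrame(rows, columns=["pathway_id", "metabolite_id"]).to_csv(
        membership_path, sep="\t", index=False
    )


def read_measurements_tsv(path) -> list[MeasurementRecord]:
    """Read a peak list: columns ``mz`` and ``mode``."""
    df = _read_tsv(path, ["mz"])
    mz = _parse_float(df, "mz", path)
    modes = df["mode"].tolist() if "mode" in df.columns else ["neutral"] * len(df)
    records = []
    for line, (m, mode) in enumerate(zip(mz, modes), start=2):
        try:
            records.append(MeasurementRecord(mz=float(m), ionization_mode=str(mode)))
        except InputError as err:
            raise InputError(f"{path}: line {line}: {err}") from err
    return records


def read_fixed_annotations_tsv(path) -> list[tuple[float, str]]:
    """Read fixed mass -> metabolite annotations (columns mass, metabolite_id)."""
    df = _read_tsv(path, ["mass", "metabolite_id"])
    masses = _parse_float(df, "mass", path)
    return list(zip(masses.tolist(), df["metabolite_id"].tolist()))


def write_pathway_posteriors(
    samples: PosteriorSamples, path, threshold: float = 0.5
) -> None:
    flags = samples.active_flags(threshold)
    pd.DataFrame(
        {
            "pathway_id": samples.pathway_ids,
            "posterior": samples.pathway_posterior,
            "active_flag": flags.astype(int),
            "mc_se": samples.mc_se,
        }
    ).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_pathway_posteriors(path) -> pd.DataFrame:
    return _read_tsv(path, ["pathway_id", "posterior", "active_flag", "mc_se"]).astype(
        {"posterior": float, "active_flag": int, "mc_se": float}
    )


def write_annotations(
    result: AnnotationResult, obs: ObservationVector, path
) -> None:
    """Per-observed-bin candidate ranking table."""
    rows = []
    for k in sorted(result.ranked_bins):
        rb = result.ranked_bins[k]
        matched = obs.matched_measurements[k]
        for rank, (met, post) in enumerate(zip(rb.metabolite_ids, rb.posteriors), start=1):
            rows.append(
                (
                    rb.bin_center,
                    matched[0] if matched else float("nan"),
                    met,
                    post,
                    rank,
                    int(met in rb.top_set),
                )
            )
    pd.DataFrame(
        rows,
        columns=[
            "bin_center",
            "matched_measurement_mass",
            "metabolite_id",
            "posterior",
            "rank",
            "in_top_set",
        ],
    ).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_annotations(path) -> pd.DataFrame:
    return _read_tsv(
        path,
        ["bin_center", "matched_measurement_mass", "metabolite_id", "posterior",
         "rank", "in_top_set"],
    ).astype({"bin_center": float, "posterior": float, "rank": int, "in_top_set": int})


def write_metabolite_posteriors(
    result: AnnotationResult, model: MetabolicModel, obs: ObservationVector, path
) -> None:
    """Full presence-posterior table over all metabolites."""
    binof = model.bin_of_metabolite
    centers = [
        float(model.bin_centers[k]) if k != NO_BIN else float("nan") for k in binof
    ]
    observed = [int(obs.w[k]) if k != NO_BIN else 0 for k in binof]
    pd.DataFrame(
        {
            "metabolite_id": result.metabolite_ids,
            "posterior": result.metabolite_posterior,
            "bin_center": centers,
            "bin_observed": observed,
        }
    ).to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_enrichment(path) -> pd.DataFrame:
    return _read_tsv(
        path, ["pathway_id", "ratio", "n_measured", "n_total", "fisher_p", "enriched"]
    ).astype({"ratio": float, "n_measured": int, "n_total": int, "fisher_p": float})
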