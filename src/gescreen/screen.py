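"""Transcriptional-similarity scoring of a plate-structured compound screen.

All normalization is within-plate: a compound's per-gene fold change is its
mean expression over that plate's vehicle-well mean, and its intraplate score
on a gene divides that fold change by the plate's positive-control (drug
cocktail) fold change.  The similarity score sums the absolute deviation of
the intraplate scores from 1 over the signature genes, so 0 means the
compound reproduces the cocktail's transcriptional effect exactly and lower
is more similar.  Whole-screen statistics are used only for control QC: a
plate is flagged when any of its control means sits strictly more than k
standard deviations from the screen-wide mean of those control means, and the
flagged plate's compounds are excluded (the software cannot repeat a wet-lab
treatment).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import PlateLibrary

__all__ = [
    "POSITIVE_CONTROL_ID",
    "normalize_plate",
    "fold_changes",
    "qc_controls",
    "similarity_score",
    "score_library",
    "rank_library",
    "filter_hits",
]

#: pseudo-compound id under which each plate's positive-control aggregate is
#: scored against itself; anchors the ranking at similarity 0
POSITIVE_CONTROL_ID = "BD_COCKTAIL"
POSITIVE_CONTROL_NAME = "BD drug combination (positive control)"


def normalize_plate(lib: PlateLibrary, plate_id: str,
                    genes: list[str]) -> pd.DataFrame:
    """Within-plate fold changes against the vehicle-well mean.

    Returns one row per (entity, gene) with columns ``plate_id, entity,
    role, gene, fc``, where entities are the plate's compounds plus the
    positive-control aggregate.  Replicate wells of a compound are averaged
    before division.
    """
    sub = lib.plate_measurements(plate_id)
    if sub.empty:
        raise ValueError(f"unknown plate {plate_id!r}")
    sub = sub[sub["gene"].isin(genes)]

    veh = sub[sub["role"] == "vehicle"].groupby("gene")["value"].mean()
    for g in genes:
        if g not in veh.index:
            raise ValueError(f"plate {plate_id!r}: no vehicle measurement for gene {g!r}")
        if veh[g] == 0:
            raise ValueError(f"plate {plate_id!r}: vehicle mean is 0 for gene {g!r}")

    rows = []
    pos = sub[sub["role"] == "positive_control"].groupby("gene")["value"].mean()
    for g in genes:
        if g not in pos.index:
            raise ValueError(
                f"plate {plate_id!r}: no positive-control measurement for gene {g!r}")
        rows.append((plate_id, POSITIVE_CONTROL_ID, "positive_control",
                     g, pos[g] / veh[g]))
    cpd = (sub[sub["role"] == "compound"]
           .groupby(["compound_id", "gene"])["value"].mean())
    for (cid, g), v in cpd.items():
        rows.append((plate_id, cid, "compound", g, v / veh[g]))
    return pd.DataFrame(rows, columns=["plate_id", "entity", "role", "gene", "fc"])


def fold_changes(lib: PlateLibrary, genes: list[str]) -> pd.DataFrame:
    """Concatenated :func:`normalize_plate` output for every plate."""
    return pd.concat([normalize_plate(lib, p, genes) for p in lib.plate_ids],
                     ignore_index=True)


def qc_controls(lib: PlateLibrary, genes: list[str],
                k: float = 2.0) -> pd.DataFrame:
    """Flag plates whose control means stray from the whole-screen mean.

    For each control role (vehicle and positive control) and gene, the
    per-plate control mean is compared with the mean and standard deviation
    of those means across the whole screen; a plate is flagged when any
    deviation strictly exceeds ``k`` standard deviations.  Returns a frame
    indexed by plate with columns ``qc_pass`` and ``qc_reason``.
    """
    plates = lib.plate_ids
    if len(plates) < 2:
        raise ValueError("control QC needs at least 2 plates")
    ctrl = lib.measurements.merge(
        lib.wells[["plate_id", "well_id", "role"]], on=["plate_id", "well_id"])
    ctrl = ctrl[ctrl["role"].isin(["vehicle", "positive_control"])
                & ctrl["gene"].isin(genes)]
    means = (ctrl.groupby(["role", "gene", "plate_id"])["value"].mean()
             .rename("m").reset_index())

    qc_pass = pd.Series(True, index=pd.Index(plates, name="plate_id"))
    reasons = pd.Series("", index=qc_pass.index)
    for (role, gene), sub in means.groupby(["role", "gene"]):
        m = sub["m"].mean()
        sd = sub["m"].std(ddof=1)
        if sd == 0:
            continue
        dev = (sub["m"] - m).abs()
        for plate in sub.loc[dev > k * sd, "plate_id"]:
            qc_pass[plate] = False
            tag = f"{role}:{gene}"
            if tag not in reasons[plate]:
                reasons[plate] = (reasons[plate] + ";" + tag).lstrip(";")
    return pd.DataFrame({"qc_pass": qc_pass, "qc_reason": reasons})


def similarity_score(fc: pd.DataFrame, compound_id: str,
                     genes: list[str]) -> float:
    """Similarity of one compound's profile to the cocktail's.

    ``s_g = FC_compound,g / FC_positive-control,g`` on the compound's plate;
    the score is ``sum_g |1 - s_g|`` — 0 iff the compound matches the
    positive-control fold changes on every signature gene.
    """
    rows = fc[(fc["entity"] == compound_id)]
    if rows.empty:
        raise KeyError(f"no fold changes for compound {compound_id!r}")
    total = 0.0
    for plate_id, sub in rows.groupby("plate_id"):
        pos = fc[(fc["plate_id"] == plate_id)
                 & (fc["entity"] == POSITIVE_CONTROL_ID)].set_index("gene")["fc"]
        comp = sub.set_index("gene")["fc"]
        for g in genes:
            if g not in comp.index:
                raise KeyError(f"compound {compound_id!r}: no fold change for gene {g!r}")
            if pos[g] == 0:
                raise ValueError(
                    f"plate {plate_id!r}: positive-control fold change is 0 for {g!r}")
            s = comp[g] / pos[g]
            total += abs(1.0 - s)
    # compounds measured on several plates are averaged over plates
    return total / rows["plate_id"].nunique()


def score_library(lib: PlateLibrary, genes: list[str],
                  k: float = 2.0) -> pd.DataFrame:
    """Fold changes, intraplate scores and similarity for every compound.

    Includes one row for the positive-control aggregate (scored against
    itself, hence similarity exactly 0 by construction of the intraplate
    score).  Returns a frame indexed by entity id with per-gene ``fc_*`` and
    ``s_*`` columns, ``similarity`` and ``qc_pass``.
    """
    fc = fold_changes(lib, genes)
    qc = qc_controls(lib, genes, k=k) if len(lib.plate_ids) >= 2 else None

    records = []
    for (entity, plate_id), sub in fc.groupby(["entity", "plate_id"]):
        pos = fc[(fc["plate_id"] == plate_id)
                 & (fc["entity"] == POSITIVE_CONTROL_ID)].set_index("gene")["fc"]
        comp = sub.set_index("gene")["fc"]
        rec = {"entity": entity, "plate_id": plate_id}
        sim = 0.0
        for g in genes:
            s = comp[g] / pos[g]
            rec[f"fc_{g}"] = comp[g]
            rec[f"s_{g}"] = s
            sim += abs(1.0 - s)
        rec["similarity"] = sim
        rec["qc_pass"] = bool(qc.loc[plate_id, "qc_pass"]) if qc is not None else True
        records.append(rec)
    out = pd.DataFrame(records)
    # a compound spread over plates: average its per-plate scores
    agg = {c: "mean" for c in out.columns if c not in ("entity", "plate_id", "qc_pass")}
    agg["qc_pass"] = "all"
    out = out.groupby("entity").agg(agg)
    out["qc_pass"] = out["qc_pass"].astype(bool)
    return out


def rank_library(scores: pd.DataFrame) -> pd.DataFrame:
    """Rank entities by ascending similarity, ties broken by entity id.

    QC-failed entities stay listed but carry ``qc_pass = False`` and are
    pre-marked excluded with reason ``failed QC``.
    """
    if scores.empty:
        raise ValueError("no scored compounds to rank")
    out = scores.sort_index().sort_values("similarity", kind="stable").copy()
    out["rank"] = np.arange(1, len(out) + 1)
    out["excluded"] = ~out["qc_pass"]
    out["reason"] = np.where(out["qc_pass"], "", "failed QC")
    return out


def filter_hits(ranking: pd.DataFrame,
                annotations: pd.DataFrame) -> pd.DataFrame:
    """Exclude unapproved, withdrawn and black-box-warning compounds.

    Every ranked compound (the positive-control aggregate aside) must be
    annotated; survivors keep their relative order.  Exclusion reasons
    combine with any prior QC exclusion.
    """
    ann = annotations.set_index("compound_id")
    out = ranking.copy()
    for entity in out.index:
        if entity == POSITIVE_CONTROL_ID:
            continue
        if entity not in ann.index:
            raise KeyError(f"compound {entity!r} has no annotation")
        row = ann.loc[entity]
        reasons = [r for r in [out.at[entity, "reason"]] if r]
        if not bool(row["approved"]):
            reasons.append("not approved")
        if bool(row["withdrawn"]):
            reasons.append("withdrawn")
        if bool(row["black_box"]):
            reasons.append("black box")
        out.at[entity, "excluded"] = bool(reasons)
        out.at[entity, "reason"] = ";".join(reasons)
    return out
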