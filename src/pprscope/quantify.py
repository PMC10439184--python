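"""Expression quantification: TPM, size-fraction merging, group decomposition.

Small (0.22--3 um) and large (3--200 um) size fractions of the same water
sample are sequenced as separate libraries, so their TPM values live on
different scales.  To compare lineage contributions per water sample, each
fraction's TPM is weighted by the RNA mass extracted per liter of seawater
from that fraction:

    merged = (TPM_small * RNA_small/L + TPM_large * RNA_large/L)
             / (RNA_small/L + RNA_large/L)

The formula is a weighted mean, hence bounded by the two inputs, and linear
in each TPM argument -- so applying it per unigene and summing equals
applying it to group sums.  Merged values are reported as "merged TPM
contribution" (TPM-equivalent units, not the TPM of any single library).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DEPTH_ORDER = ("SUR", "DCM", "BOT")
FRACTIONS = ("small", "large")

GROUPINGS = ("domain", "supergroup", "spectral_class", "family")
_GROUP_COLUMN = {
    "domain": "domain_call",
    "supergroup": "supergroup",
    "spectral_class": "spectral_class",
    "family": "family",
}


def compute_tpm(counts, effective_lengths) -> np.ndarray:
    """Length-normalized transcripts-per-million from raw counts.

    TPM_i = (counts_i / length_i) / sum_j (counts_j / length_j) * 1e6.
    An all-zero count vector yields all-zero TPM.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(effective_lengths, dtype=float)
    if counts.shape != lengths.shape:
        raise ValueError("counts and effective_lengths must have the same shape")
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be positive")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    rate = counts / lengths
    total = rate.sum()
    if total == 0:
        return np.zeros_like(rate)
    return rate / total * 1e6


def compute_tpm_table(
    counts: pd.DataFrame, effective_lengths: Mapping[str, float] | pd.Series
) -> pd.DataFrame:
    """Per-column TPM of a unigenes x samples count table."""
    lengths = pd.Series(effective_lengths).reindex(counts.index)
    if lengths.isna().any():
        missing = counts.index[lengths.isna()].tolist()
        raise ValueError(f"missing effective lengths for {missing}")
    return counts.apply(lambda col: pd.Series(compute_tpm(col, lengths), col.index))


def merge_fractions(tpm_small, tpm_large, rna_small_per_l, rna_large_per_l):
    """RNA-yield-weighted mean of small- and large-fraction TPM.

    Accepts scalars or broadcastable arrays.  Both yields must be positive
    (one missing fraction is handled upstream by falling back to the present
    fraction).
    """
    tpm_small = np.asarray(tpm_small, dtype=float)
    tpm_large = np.asarray(tpm_large, dtype=float)
    rna_s = np.asarray(rna_small_per_l, dtype=float)
    rna_l = np.asarray(rna_large_per_l, dtype=float)
    if (tpm_small < 0).any() or (tpm_large < 0).any():
        raise ValueError("TPM values must be non-negative")
    if (rna_s < 0).any() or (rna_l < 0).any():
        raise ValueError("RNA yields must be non-negative")
    if ((rna_s + rna_l) == 0).any():
        raise ValueError("both RNA yields are zero; merged value undefined")
    merged = (tpm_small * rna_s + tpm_large * rna_l) / (rna_s + rna_l)
    return merged if merged.ndim else float(merged)


def read_sample_meta(path_or_df) -> pd.DataFrame:
    """Load and validate the sample metadata table.

    Columns: sample_id, station, depth_layer, fraction, replicate,
    rna_yield_per_liter, volume_filtered_liters.  Each (station, depth_layer,
    replicate) water sample may carry at most one record per fraction.
    """
    if isinstance(path_or_df, pd.DataFrame):
        meta = path_or_df.copy()
    else:
        meta = pd.read_csv(path_or_df, sep="\t")
    required = {
        "sample_id",
        "station",
        "depth_layer",
        "fraction",
        "replicate",
        "rna_yield_per_liter",
    }
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"sample metadata missing columns: {sorted(missing)}")
    bad_frac = set(meta["fraction"]) - set(FRACTIONS)
    if bad_frac:
        raise ValueError(f"unknown size fractions: {sorted(bad_frac)}")
    if (meta["rna_yield_per_liter"] <= 0).any():
        raise ValueError("rna_yield_per_liter must be positive")
    dup = meta.duplicated(["station", "depth_layer", "replicate", "fraction"])
    if dup.any():
        raise ValueError(
            "duplicate fraction records for water sample(s): "
            f"{meta.loc[dup, 'sample_id'].tolist()}"
        )
    meta["water_sample_id"] = (
        meta["station"].astype(str)
        + "_"
        + meta["depth_layer"].astype(str)
        + "_"
        + meta["replicate"].astype(str)
    )
    return meta


def merge_unigene_tpm(
    tpm_small: pd.DataFrame, tpm_large: pd.DataFrame, meta: pd.DataFrame
) -> pd.DataFrame:
    """Per-unigene merged TPM contribution, water samples x unigenes.

    Both TPM tables are unigenes x fraction-sample-ids.  Missing fractions
    fall back to the present one.
    """
    meta = read_sample_meta(meta)
    unigenes = tpm_small.index.union(tpm_large.index)
    rows = {}
    for wsid, grp in meta.groupby("water_sample_id", sort=True):
        frac = {r.fraction: r for r in grp.itertuples(index=False)}
        vals = {}
        for name, table in (("small", tpm_small), ("large", tpm_large)):
            if name in frac:
                col = frac[name].sample_id
                if col not in table.columns:
                    raise ValueError(f"sample {col!r} absent from {name} TPM table")
                vals[name] = table[col].reindex(unigenes).fillna(0.0)
        if set(vals) == {"small", "large"}:
            rows[wsid] = merge_fractions(
                vals["small"].to_numpy(),
                vals["large"].to_numpy(),
                frac["small"].rna_yield_per_liter,
                frac["large"].rna_yield_per_liter,
            )
        else:
            (only,) = vals.values()
            rows[wsid] = only.to_numpy()
    return pd.DataFrame.from_dict(rows, orient="index", columns=unigenes)


def group_contributions(
    calls: pd.DataFrame,
    tpm_small: pd.DataFrame,
    tpm_large: pd.DataFrame,
    meta: pd.DataFrame,
    grouping: str = "domain",
    ppr_only: bool = False,
) -> pd.DataFrame:
    """Merged per-group rhodopsin contribution and share per water sample.

    ``calls`` must carry the grouping column (``domain_call``, ``supergroup``,
    ``spectral_class`` or ``family``); unigenes absent from ``calls`` are
    treated as non-rhodopsin and excluded.  Output columns:
    water_sample_id, group, merged_tpm, pct_share, n_unigenes,
    fractions_present (flags water samples missing one fraction).
    """
    if grouping not in GROUPINGS:
        raise ValueError(f"grouping must be one of {GROUPINGS}")
    col = _GROUP_COLUMN[grouping]
    if col not in calls.columns:
        raise ValueError(f"calls table lacks column {col!r} for grouping {grouping!r}")
    calls = calls.copy()
    if ppr_only and "is_ppr" in calls.columns:
        calls = calls[calls["is_ppr"].astype(bool)]
    labels = calls.set_index("unigene_id")[col].fillna("unassigned")
    meta = read_sample_meta(meta)
    groups = sorted(labels.unique())

    def _group_sums(table: pd.DataFrame, sample_id: str) -> pd.Series:
        vec = table[sample_id].reindex(labels.index).fillna(0.0)
        return vec.groupby(labels).sum().reindex(groups, fill_value=0.0)

    records = []
    counts = labels.value_counts().reindex(groups, fill_value=0)
    for wsid, grp in meta.groupby("water_sample_id", sort=True):
        frac = {r.fraction: r for r in grp.itertuples(index=False)}
        sums = {}
        for name, table in (("small", tpm_small), ("large", tpm_large)):
            if name in frac and frac[name].sample_id in table.columns:
                sums[name] = _group_sums(table, frac[name].sample_id)
        present = "+".join(sorted(sums))
        if set(sums) == {"small", "large"}:
            merged = merge_fractions(
                sums["small"].to_numpy(),
                sums["large"].to_numpy(),
                frac["small"].rna_yield_per_liter,
                frac["large"].rna_yield_per_liter,
            )
            merged = pd.Series(merged, index=groups)
        elif sums:
            (merged,) = sums.values()
        else:
            raise ValueError(f"water sample {wsid!r} has no fraction data")
        total = merged.sum()
        for g in groups:
            records.append(
                {
                    "water_sample_id": wsid,
                    "group": g,
                    "merged_tpm": float(merged[g]),
                    "pct_share": 100.0 * merged[g] / total if total > 0 else 0.0,
                    "n_unigenes": int(counts[g]),
                    "fractions_present": present,
                }
            )
    return pd.DataFrame(records)


def spectral_depth_profile(
    calls: pd.DataFrame,
    tpm_small: pd.DataFrame,
    tpm_large: pd.DataFrame,
    meta: pd.DataFrame,
    classes: Sequence[str] = ("BPR", "GPR"),
) -> pd.DataFrame:
    """Long-format BPR/GPR expression by station x depth x fraction.

    One row per (station, depth_layer, fraction, replicate, spectral_class)
    with the summed TPM of that class in that library; classes absent from a
    sample appear with 0.
    """
    labels = calls.set_index("unigene_id")["spectral_class"]
    meta = read_sample_meta(meta)
    records = []
    for row in meta.itertuples(index=False):
        table = tpm_small if row.fraction == "small" else tpm_large
        if row.sample_id not in table.columns:
            continue
        vec = table[row.sample_id].reindex(labels.index).fillna(0.0)
        sums = vec.groupby(labels).sum()
        for cls in classes:
            records.append(
                {
                    "station": row.station,
                    "depth_layer": row.depth_layer,
                    "fraction": row.fraction,
                    "replicate": row.replicate,
                    "spectral_class": cls,
                    "tpm": float(sums.get(cls, 0.0)),
                }
            )
    return pd.DataFrame(records)


def depth_trend(profile: pd.DataFrame, spectral_class: str) -> str:
    """Direction of the mean expression trend over SUR -> DCM -> BOT.

    Returns ``"increasing"``, ``"decreasing"`` or ``"none"`` based on strict
    monotonicity of the per-depth means (replicates, stations and fractions
    pooled).
    """
    sub = profile[profile["spectral_class"] == spectral_class]
    means = [
        sub.loc[sub["depth_layer"] == d, "tpm"].mean() for d in DEPTH_ORDER
    ]
    if any(np.isnan(m) for m in means):
        return "none"
    if means[0] < means[1] < means[2]:
        return "increasing"
    if means[0] > means[1] > means[2]:
        return "decreasing"
    return "none"
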