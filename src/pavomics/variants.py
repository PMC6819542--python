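"""Sequence-variant quality control and ePAV-variant linkage disequilibrium.

The QC cascade runs in a fixed order on raw per-(variant, inbred, tissue)
call records: mapping-quality gate (MQ < 55 removes the variant), per-call
depth gate (depth < 5 sets the call to NA), per-variant heterozygosity gate
(> 10% het calls among non-NA calls discards the variant, residual het
calls become NA), biallelic gate, a <= 20% missing gate at the inbred
level, cross-tissue reconciliation (conflicting calls resolved to the
higher-depth call, ties to NA), and finally column-mean imputation of the
remaining NAs.  Re-running the cascade on its own output changes nothing.

LD between an ePAV gene's presence/absence vector and variants is the
squared Pearson correlation of the coded vectors; the profile splits each
gene's strongest correlate into *linked* (within 100 kb of the gene) and
*unlinked* scopes and bins the r2max values into five classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pav_calling import ABSENT, PACallMatrix, PRESENT

__all__ = [
    "VariantMatrix",
    "filter_variants",
    "reconcile_tissues",
    "ld_r2",
    "ld_profile",
    "epav_vector_matrix",
    "R2_BINS",
]

MQ_MIN = 55
DEPTH_MIN = 5
HET_MAX = 0.10
MISSING_MAX = 0.20

#: r2max classes, highest first: [1.0,0.8], (0.8,0.6], ... (0.2,0]
R2_BINS = [(0.8, 1.0), (0.6, 0.8), (0.4, 0.6), (0.2, 0.4), (0.0, 0.2)]
R2_BIN_LABELS = ["[1.0,0.8]", "(0.8,0.6]", "(0.6,0.4]", "(0.4,0.2]", "(0.2,0]"]


@dataclass
class VariantMatrix:
    """Post-QC biallelic variants: variant x inbred allele dosages in
    {0, 1} with NAs replaced by the column (variant) mean, plus positions
    and a per-variant QC log accounting for every dropped variant."""

    alleles: pd.DataFrame
    positions: pd.DataFrame
    qc_log: pd.DataFrame = field(default_factory=pd.DataFrame)


def reconcile_tissues(calls: list[tuple[str, int]]) -> str:
    """One call per inbred from its per-tissue (allele, depth) pairs.

    Identical calls pass through; conflicts go to the higher-depth call;
    depth ties between different alleles give NA ('').
    """
    real = [(a, d) for a, d in calls if a]
    if not real:
        return ""
    alleles = {a for a, _ in real}
    if len(alleles) == 1:
        return real[0][0]
    best = max(d for _, d in real)
    top = {a for a, d in real if d == best}
    return top.pop() if len(top) == 1 else ""


def filter_variants(raw: pd.DataFrame) -> VariantMatrix:
    """Apply the QC cascade to a raw call table.

    ``raw`` columns: variant_id, chrom, pos, inbred, tissue, allele
    (empty string = no call), mapping_quality, depth, is_het.
    """
    required = {"variant_id", "chrom", "pos", "inbred", "allele", "mapping_quality", "depth"}
    missing_cols = required - set(raw.columns)
    if missing_cols:
        raise ValueError(f"raw table lacks columns: {sorted(missing_cols)}")
    df = raw.copy()
    if "tissue" not in df:
        df["tissue"] = "all"
    if "is_het" not in df:
        df["is_het"] = False
    inbreds = sorted(df["inbred"].unique())
    log_rows = []
    kept_rows: dict[str, pd.Series] = {}
    positions: list[tuple[str, str, int]] = []

    for vid, sub in df.groupby("variant_id", sort=True):
        if (sub["mapping_quality"] < MQ_MIN).any():
            log_rows.append((vid, "removed_low_mq"))
            continue
        sub = sub.copy()
        sub.loc[sub["depth"] < DEPTH_MIN, "allele"] = ""
        called = sub["allele"] != ""
        n_called = int(called.sum())
        if n_called:
            het_frac = float((sub.loc[called, "is_het"]).mean())
            if het_frac > HET_MAX:
                log_rows.append((vid, "removed_heterozygosity"))
                continue
        sub.loc[sub["is_het"].astype(bool), "allele"] = ""
        observed = sorted(set(sub.loc[sub["allele"] != "", "allele"]))
        if len(observed) > 2:
            log_rows.append((vid, "removed_not_biallelic"))
            continue
        if len(observed) == 0:
            log_rows.append((vid, "removed_all_calls_na"))
            continue
        # inbred-level missingness before reconciliation: an inbred is
        # missing when none of its tissue records carries a call
        per_inbred = {
            s: list(zip(g["allele"], g["depth"])) for s, g in sub.groupby("inbred")
        }
        n_missing = sum(
            1 for s in inbreds
            if not any(a for a, _ in per_inbred.get(s, []))
        )
        if n_missing / len(inbreds) > MISSING_MAX:
            log_rows.append((vid, "removed_missing"))
            continue
        calls = {s: reconcile_tissues(per_inbred.get(s, [])) for s in inbreds}
        code = {a: float(i) for i, a in enumerate(observed)}
        vec = pd.Series(
            [code[calls[s]] if calls[s] else np.nan for s in inbreds],
            index=inbreds, name=vid,
        )
        if vec.isna().mean() > MISSING_MAX:
            log_rows.append((vid, "removed_missing"))
            continue
        vec = vec.fillna(vec.mean())
        kept_rows[vid] = vec
        positions.append((vid, sub["chrom"].iloc[0], int(sub["pos"].iloc[0])))
        log_rows.append((vid, "retained"))

    alleles = (
        pd.DataFrame(kept_rows).T
        if kept_rows
        else pd.DataFrame(columns=inbreds, dtype=float)
    )
    pos = pd.DataFrame(positions, columns=["variant_id", "chrom", "pos"]).set_index(
        "variant_id", drop=False
    )
    log = pd.DataFrame(log_rows, columns=["variant_id", "rule"]).set_index("variant_id")
    return VariantMatrix(alleles, pos, log)


def ld_r2(x: np.ndarray | pd.Series, y: np.ndarray | pd.Series) -> float:
    """Squared Pearson correlation between two coded vectors over the same
    inbreds (symmetric, invariant to allele relabeling).  Zero variance in
    either vector gives NaN with a warning."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must cover the same inbreds")
    if x.std() == 0 or y.std() == 0:
        warnings.warn("zero variance: r2 undefined", RuntimeWarning, stacklevel=2)
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def epav_vector_matrix(consensus: PACallMatrix, genes: list) -> pd.DataFrame:
    """Code consensus calls present=1 / absent=0 per gene; no-calls are
    imputed with the gene's mean coded value."""
    sub = consensus.calls.loc[genes]
    arr = sub.to_numpy(dtype=float)
    coded = np.where(arr == PRESENT, 1.0, np.where(arr == ABSENT, 0.0, np.nan))
    means = np.nanmean(np.where(np.isnan(coded), np.nan, coded), axis=1)
    idx = np.where(np.isnan(coded))
    coded[idx] = np.take(means, idx[0])
    return pd.DataFrame(coded, index=sub.index, columns=sub.columns)


def _r2_rows(target: np.ndarray, sv: np.ndarray) -> np.ndarray:
    """r2 of one coded vector against every row of sv (NaN where either side
    has zero variance)."""
    n = target.size
    t = target - target.mean()
    st = t.std()
    s = sv - sv.mean(axis=1, keepdims=True)
    ss = s.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (s @ t) / n / (ss * st)
    r2 = r * r
    r2[(ss == 0)] = np.nan
    if st == 0:
        r2[:] = np.nan
    return r2


def _bin_percentages(values: np.ndarray) -> list[float]:
    values = values[~np.isnan(values)]
    if values.size == 0:
        return [float("nan")] * len(R2_BINS)
    values = np.clip(values, 0.0, 1.0)  # guard float round-off at r2 = 1
    out = []
    for i, (lo, hi) in enumerate(R2_BINS):
        if i == len(R2_BINS) - 1:
            mask = (values >= 0) & (values <= hi)
        else:
            mask = (values > lo) & (values <= hi)
        out.append(100.0 * mask.sum() / values.size)
    return out


def ld_profile(
    consensus: PACallMatrix,
    epav_genes: list,
    gene_positions: pd.DataFrame,
    sv: VariantMatrix,
    window: int = 100_000,
) -> pd.DataFrame:
    """Distribution of r2max between ePAV genes (and their closest variant)
    and linked / unlinked variants.

    For each ePAV gene, *linked* variants lie within ``window`` bp of the
    gene's boundaries on the same chromosome and *unlinked* variants
    outside; r2max is taken per scope and binned.  The same is computed for
    the variant closest to each gene (excluding itself).  Returns a
    4 x 5 table of percentages (rows sum to 100), with the per-row counts
    of genes lacking any variant in a scope in ``.attrs['n_excluded']``.
    """
    common = [s for s in consensus.calls.columns if s in sv.alleles.columns]
    if len(common) < 3:
        raise ValueError("need at least 3 shared inbreds between ePAV and SV")
    genes = [g for g in epav_genes if g in gene_positions.index]
    E = epav_vector_matrix(consensus, genes)[common].to_numpy()
    S = sv.alleles[common].to_numpy()
    chrom = sv.positions["chrom"].to_numpy()
    pos = sv.positions["pos"].to_numpy()

    rows = {k: [] for k in ("epav_linked", "epav_unlinked", "closest_linked", "closest_unlinked")}
    excluded = {k: 0 for k in rows}
    for i, g in enumerate(genes):
        rec = gene_positions.loc[g]
        same = chrom == rec["chrom"]
        linked = same & (pos >= rec["start"] - window) & (pos <= rec["end"] + window)
        r2 = _r2_rows(E[i], S)
        for scope, mask in (("epav_linked", linked), ("epav_unlinked", ~linked)):
            vals = r2[mask]
            vals = vals[~np.isnan(vals)]
            if vals.size:
                rows[scope].append(vals.max())
            else:
                excluded[scope] += 1
        # closest variant to the gene, then its r2max to the other variants
        if same.any():
            mid = (rec["start"] + rec["end"]) / 2.0
            d = np.where(same, np.abs(pos - mid), np.inf)
            j = int(np.argmin(d))
            r2c = _r2_rows(S[j], S)
            r2c[j] = np.nan
            linked_c = (chrom == chrom[j]) & (np.abs(pos - pos[j]) <= window)
            linked_c[j] = False
            for scope, mask in (("closest_linked", linked_c), ("closest_unlinked", ~linked_c)):
                vals = r2c[mask]
                vals = vals[~np.isnan(vals)]
                if vals.size:
                    rows[scope].append(vals.max())
                else:
                    excluded[scope] += 1
        else:
            excluded["closest_linked"] += 1
            excluded["closest_unlinked"] += 1

    table = pd.DataFrame(
        {scope: _bin_percentages(np.array(vals, dtype=float)) for scope, vals in rows.items()},
        index=R2_BIN_LABELS,
    ).T
    table.attrs["n_excluded"] = excluded
    table.attrs["r2max"] = {k: np.array(v) for k, v in rows.items()}
    return table
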