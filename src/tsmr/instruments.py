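"""Instrumental-variable selection for two-sample MR.

The pipeline applies, in order: (i) a genome-wide significance threshold,
(ii) greedy LD clumping, (iii) an F-statistic strength filter, and — after
harmonization against the outcome — (iv) Steiger directionality filtering.
Each step returns a subset of its input, so instrument counts shrink
monotonically and every exclusion is attributable to one criterion.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import HarmonizedSet, SummaryStatSet

GWAS_SIGNIFICANCE = 5e-8
CLUMP_R2 = 0.001
CLUMP_KB = 10_000
F_MIN = 10.0


class NoInstrumentsError(RuntimeError):
    """Raised when selection leaves an empty instrument set."""


def select_significant(sset: SummaryStatSet, threshold: float = GWAS_SIGNIFICANCE) -> SummaryStatSet:
    """Keep variants associated with the trait at ``pval < threshold``."""
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    kept = sset.df[sset.df["pval"] < threshold].reset_index(drop=True)
    return SummaryStatSet(df=kept, trait=sset.trait)


def load_ld(path, ids=None) -> pd.DataFrame:
    """Load an LD r² table as a square DataFrame indexed by variant id.

    Accepts either a square delimited table (header + index column of
    variant ids) or a triplet list with columns (id_i, id_j, r2).  With
    ``ids`` given, the matrix is restricted to those variants — the cheap
    path when clumping only a significant subset.
    """
    probe = pd.read_csv(path, sep="\t", nrows=0)
    if {"id_i", "id_j", "r2"} <= set(probe.columns):
        trip = pd.read_csv(path, sep="\t")
        if ids is not None:
            ids = list(ids)
            universe = set(ids)
            trip = trip[trip["id_i"].isin(universe) & trip["id_j"].isin(universe)]
            covered = set(trip["id_i"]) | set(trip["id_j"])
            all_ids = [v for v in ids if v in covered]
        else:
            all_ids = sorted(set(trip["id_i"]) | set(trip["id_j"]))
        pos = {v: i for i, v in enumerate(all_ids)}
        mat = np.eye(len(all_ids))
        ii = trip["id_i"].map(pos).to_numpy()
        jj = trip["id_j"].map(pos).to_numpy()
        mat[ii, jj] = trip["r2"].to_numpy()
        mat[jj, ii] = trip["r2"].to_numpy()
        return pd.DataFrame(mat, index=all_ids, columns=all_ids)
    mat = pd.read_csv(path, sep="\t", index_col=0)
    if ids is not None:
        present = [v for v in ids if v in mat.index]
        mat = mat.loc[present, present]
    return mat


def ld_clump(
    sset: SummaryStatSet,
    ld: pd.DataFrame,
    r2_max: float = CLUMP_R2,
    window_kb: float = CLUMP_KB,
    missing: str = "error",
) -> SummaryStatSet:
    """Greedy p-value-ranked LD clumping.

    Variants are visited in ascending p-value order (ties broken by
    variant id for determinism); each kept variant removes every remaining
    variant on the same chromosome within ``window_kb`` whose r² with it is
    ≥ ``r2_max``.  ``ld`` is a square r² table indexed by variant id;
    variants missing from it raise by default (``missing="independent"``
    treats them as unlinked).
    """
    df = sset.df
    if df.empty:
        return SummaryStatSet(df=df.copy(), trait=sset.trait)
    absent = set(df["variant_id"]) - set(ld.index)
    if absent:
        if missing == "error":
            raise KeyError(f"variant(s) absent from LD matrix: {sorted(absent)[:5]} ...")
        if missing != "independent":
            raise ValueError("missing must be 'error' or 'independent'")

    order = df.sort_values(["pval", "variant_id"], kind="mergesort")
    kept_ids: list[str] = []
    removed: set[str] = set()
    ids_in_ld = [v for v in df["variant_id"] if v in ld.index]
    sub = ld.loc[ids_in_ld, ids_in_ld] if ids_in_ld else ld
    meta = df.set_index("variant_id")[["chrom", "pos"]]
    for rec in order.itertuples(index=False):
        vid = rec.variant_id
        if vid in removed:
            continue
        kept_ids.append(vid)
        if vid not in sub.index:
            continue
        linked = sub.loc[vid]
        for other, r2 in linked.items():
            if other == vid or other in removed or other in kept_ids:
                continue
            if r2 >= r2_max and meta.loc[other, "chrom"] == rec.chrom and abs(
                meta.loc[other, "pos"] - rec.pos
            ) <= window_kb * 1000:
                removed.add(other)
    kept = df[df["variant_id"].isin(kept_ids)].reset_index(drop=True)
    return SummaryStatSet(df=kept, trait=sset.trait)


def apply_exclusion_list(sset: SummaryStatSet, excluded) -> SummaryStatSet:
    """Remove user-supplied variants (e.g. known confounder associations).

    ``excluded`` is an iterable of variant ids or a path to a file with one
    id per line.
    """
    if isinstance(excluded, (str, bytes)) or hasattr(excluded, "read_text"):
        with open(excluded) as fh:
            excluded = {line.strip() for line in fh if line.strip()}
    else:
        excluded = set(excluded)
    kept = sset.df[~sset.df["variant_id"].isin(excluded)].reset_index(drop=True)
    return SummaryStatSet(df=kept, trait=sset.trait)


def f_statistic(beta, se):
    """Instrument strength F = beta²/se²; F ≤ 10 marks a weak instrument."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    out = (beta / se) ** 2
    return float(out) if out.ndim == 0 else out


def filter_by_f(sset: SummaryStatSet, f_min: float = F_MIN) -> SummaryStatSet:
    """Exclude instruments with F ≤ f_min (weak-instrument guard)."""
    f = f_statistic(sset.df["beta"].to_numpy(), sset.df["se"].to_numpy())
    kept = sset.df[f > f_min].reset_index(drop=True)
    return SummaryStatSet(df=kept, trait=sset.trait)


def variance_explained(eaf, beta):
    """Per-SNP variance explained in a standardized trait: 2·MAF·(1−MAF)·β².

    The instrument-set R² is the sum of these contributions.
    """
    eaf = np.asarray(eaf, dtype=float)
    if np.any((eaf <= 0) | (eaf >= 1)):
        raise ValueError("eaf must lie in (0, 1)")
    beta = np.asarray(beta, dtype=float)
    maf = np.minimum(eaf, 1.0 - eaf)
    out = 2.0 * maf * (1.0 - maf) * beta ** 2
    return float(out) if out.ndim == 0 else out


def steiger_filter(h: HarmonizedSet, n_x: float | None = None, n_y: float | None = None):
    """Drop instruments that explain more outcome than exposure variance.

    Exposure variance explained uses 2·MAF·(1−MAF)·β² (standardized trait);
    the outcome — binary, on the observed scale — uses r² = z²/(z²+n).  A
    per-SNP directionality p-value comes from the two-sample comparison of
    the implied correlations via Fisher's z-transform.

    Returns ``(filtered HarmonizedSet, per-SNP record DataFrame)``.
    """
    n_x = n_x if n_x is not None else h.n_x
    n_y = n_y if n_y is not None else h.n_y
    if n_x is None or np.isnan(n_x):
        raise ValueError("sample size missing for exposure")
    if n_y is None or np.isnan(n_y):
        raise ValueError("sample size missing for outcome")
    df = h.df
    r2_x = variance_explained(df["eaf"].to_numpy(), df["beta_x"].to_numpy())
    z_y = (df["beta_y"] / df["se_y"]).to_numpy()
    r2_y = z_y ** 2 / (z_y ** 2 + n_y)
    r_x = np.sqrt(np.clip(r2_x, 0, 1 - 1e-15))
    r_y = np.sqrt(np.clip(r2_y, 0, 1 - 1e-15))
    z_stat = (np.arctanh(r_x) - np.arctanh(r_y)) / np.sqrt(1.0 / (n_x - 3) + 1.0 / (n_y - 3))
    steiger_p = 2.0 * stats.norm.sf(np.abs(z_stat))
    keep = r2_y <= r2_x
    record = pd.DataFrame(
        {
            "variant_id": df["variant_id"],
            "r2_exposure": r2_x,
            "r2_outcome": r2_y,
            "steiger_keep": keep,
            "steiger_p": np.clip(steiger_p, np.nextafter(0, 1), 1.0),
        }
    )
    filtered = HarmonizedSet(
        df=df[keep].reset_index(drop=True),
        audit=h.audit,
        n_x=h.n_x,
        n_y=h.n_y,
    )
    return filtered, record


def instrument_table(sset: SummaryStatSet) -> pd.DataFrame:
    """Per-instrument audit columns: F statistic and variance explained."""
    df = sset.df.copy()
    df["f_stat"] = f_statistic(df["beta"].to_numpy(), df["se"].to_numpy())
    df["r2"] = variance_explained(df["eaf"].to_numpy(), df["beta"].to_numpy())
    return df
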