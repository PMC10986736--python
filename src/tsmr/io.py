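"""Reading, validation and harmonization of GWAS summary statistics.

Summary statistics travel as tab-delimited text with a canonical header::

    variant_id chrom pos effect_allele other_allele eaf beta se pval n n_case n_control

``n_case``/``n_control`` are optional (binary traits only).  Harmonization
aligns an outcome (and any additional exposures) to the exposure's effect
allele, the step that precedes every two-sample MR estimate: effects must
refer to the same allele before a Wald ratio means anything.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

CANONICAL_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
    "n_case",
    "n_control",
]

MANDATORY_COLUMNS = CANONICAL_COLUMNS[:10]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: default effect-allele-frequency window inside which a palindromic (A/T or
#: C/G) variant is considered unresolvable by frequency and dropped
PALINDROME_AMBIGUITY_WINDOW = (0.42, 0.58)


class FormatError(ValueError):
    """Raised when a summary-statistics file violates the format contract."""


class AmbiguityError(ValueError):
    """Raised when duplicate variant ids make harmonization ambiguous."""


@dataclass
class SummaryStatSet:
    """One trait's per-variant association table.

    Parameters
    ----------
    df
        Table with the canonical columns.  ``beta`` is the per-allele effect
        on the standardized trait (SD units) or on the log-odds scale for a
        binary trait; ``se`` its standard error; ``eaf`` the effect-allele
        frequency.
    trait
        Free-text trait label used in reports.
    rejects
        Rows that failed validation on read, with a ``reject_reason`` column.
    """

    df: pd.DataFrame
    trait: str = ""
    rejects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=CANONICAL_COLUMNS + ["reject_reason"])
    )

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in ("n_case", "n_control"):
            if col not in df.columns:
                df[col] = np.nan
        missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")
        self.df = df[CANONICAL_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sample_size(self) -> float:
        """Median per-variant sample size (GWAS tables may vary per SNP)."""
        return float(self.df["n"].median()) if len(self.df) else float("nan")


def is_palindromic(a1: str, a2: str) -> bool:
    """A/T and C/G pairs cannot be strand-resolved from alleles alone."""
    return _COMPLEMENT.get(a1) == a2


def read_sumstats(path, column_map: dict | None = None, trait: str = "") -> SummaryStatSet:
    """Read a delimited summary-statistics table.

    ``column_map`` maps nonstandard headers to canonical names, e.g.
    ``{"SNP": "variant_id", "A1": "effect_allele"}``.  Malformed rows are
    routed to ``.rejects`` with a reason, never silently dropped.
    """
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise FormatError(f"empty file: {path}")
    sep = "\t" if "\t" in first else ","
    # round_trip parsing keeps write->read->write byte-stable
    df = pd.read_csv(path, sep=sep, dtype={"chrom": str},
                     float_precision="round_trip")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")
    for col in ("n_case", "n_control"):
        if col not in df.columns:
            df[col] = np.nan
    df = df[CANONICAL_COLUMNS]
    df["chrom"] = df["chrom"].astype(str)

    reasons = _row_reject_reasons(df)
    ok = reasons == ""
    rejects = df.loc[~ok].copy()
    rejects["reject_reason"] = reasons[~ok]
    clean = df.loc[ok].reset_index(drop=True)
    return SummaryStatSet(df=clean, trait=trait, rejects=rejects.reset_index(drop=True))


def _row_reject_reasons(df: pd.DataFrame) -> pd.Series:
    reasons = pd.Series("", index=df.index, dtype=object)

    def flag(mask, reason):
        mask = mask.fillna(True) if hasattr(mask, "fillna") else mask
        reasons[mask & (reasons == "")] = reason

    num = {c: pd.to_numeric(df[c], errors="coerce") for c in ("eaf", "beta", "se", "pval", "n")}
    flag(num["se"].isna() | (num["se"] <= 0), "nonpositive se")
    flag(num["eaf"].isna() | (num["eaf"] <= 0) | (num["eaf"] >= 1), "eaf out of range")
    flag(num["pval"].isna() | (num["pval"] <= 0) | (num["pval"] > 1), "pval out of range")
    flag(num["beta"].isna(), "missing beta")
    flag(num["n"].isna() | (num["n"] <= 0), "nonpositive n")
    alleles_ok = (
        df["effect_allele"].isin(list("ACGT"))
        & df["other_allele"].isin(list("ACGT"))
        & (df["effect_allele"] != df["other_allele"])
    )
    flag(~alleles_ok, "invalid allele pair")
    return reasons


def write_sumstats(sset: SummaryStatSet, path) -> None:
    """Write tab-delimited with canonical column order and repr-roundtrip floats."""
    sset.df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def validate_sumstats(sset: SummaryStatSet, strict: bool = False) -> list[dict]:
    """Return one violation record per failed row invariant.

    With ``strict=True`` the two-sided normal relation between ``beta/se``
    and ``pval`` is also enforced (absolute tolerance 1e-6 on the p-value);
    real GWAS tables round p-values, so the check is off by default.
    """
    df = sset.df
    violations: list[dict] = []

    def add(mask: pd.Series, rule: str) -> None:
        for vid in df.loc[mask, "variant_id"]:
            violations.append({"variant_id": vid, "rule": rule})

    add(df["se"] <= 0, "nonpositive se")
    add((df["eaf"] <= 0) | (df["eaf"] >= 1), "eaf out of range")
    add((df["pval"] <= 0) | (df["pval"] > 1), "pval out of range")
    add(df["effect_allele"] == df["other_allele"], "identical alleles")
    if strict:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = df["beta"] / df["se"]
            p_expect = 2.0 * stats.norm.sf(np.abs(z))
        add(np.abs(p_expect - df["pval"]) > 1e-6, "pval inconsistent with beta/se")
    return violations


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

@dataclass
class HarmonizedSet:
    """Exposure/outcome effects aligned to the exposure's effect allele.

    ``df`` holds one row per retained instrument with columns ``variant_id,
    chrom, pos, eaf, beta_x, se_x, pval_x, beta_y, se_y, pval_y`` plus
    ``beta_<name>, se_<name>`` for any additional exposure.  ``audit`` keeps
    one row per exposure variant with its ``alignment_action`` (kept,
    flipped, dropped_palindromic, dropped_missing, dropped_mismatch) so that
    exclusions stay auditable.
    """

    df: pd.DataFrame
    audit: pd.DataFrame
    n_x: float = float("nan")
    n_y: float = float("nan")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def action_counts(self) -> dict:
        return self.audit["alignment_action"].value_counts().to_dict()


def _align_one(ea_x, oa_x, ea_y, oa_y, eaf_x, eaf_y, window) -> tuple[str, bool]:
    """Return (action, flip) for one outcome record against the exposure's alleles."""
    if is_palindromic(ea_x, oa_x):
        lo, hi = window
        if (lo <= eaf_x <= hi) or (lo <= eaf_y <= hi):
            return "dropped_palindromic", False
        if {ea_y, oa_y} != {ea_x, oa_x}:
            return "dropped_mismatch", False
        # strand is unknowable and allele labels carry no information: the
        # outcome's effect allele is matched to the exposure's purely by
        # which side of 0.5 its frequency falls on
        same_orientation = (eaf_x < 0.5) == (eaf_y < 0.5)
        return ("kept", False) if same_orientation else ("flipped", True)
    if {ea_y, oa_y} == {ea_x, oa_x}:
        return ("kept", False) if ea_y == ea_x else ("flipped", True)
    comp = {_COMPLEMENT[ea_y], _COMPLEMENT[oa_y]}
    if comp == {ea_x, oa_x}:
        return ("kept", False) if _COMPLEMENT[ea_y] == ea_x else ("flipped", True)
    return "dropped_mismatch", False


def harmonize_pair(
    exposure: SummaryStatSet,
    outcome: SummaryStatSet,
    palindrome_window: tuple[float, float] = PALINDROME_AMBIGUITY_WINDOW,
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect allele, SNP by SNP.

    Only the intersection of variant ids is considered — variants absent
    from the outcome are recorded as ``dropped_missing``, never replaced by
    LD proxies.  When the outcome's effect allele is the exposure's other
    allele the outcome beta is sign-flipped and its frequency complemented.
    Complement-strand records (A<->T, C<->G re-coding) are resolved through
    the allele pair; palindromic variants are resolved by allele frequency
    outside ``palindrome_window`` and dropped inside it.  Irreconcilable
    allele pairs are ``dropped_mismatch``.
    """
    for name, sset in (("exposure", exposure), ("outcome", outcome)):
        if sset.df["variant_id"].duplicated().any():
            dup = sset.df.loc[sset.df["variant_id"].duplicated(), "variant_id"].iloc[0]
            raise AmbiguityError(f"duplicate variant_id in {name} set: {dup}")

    out = outcome.df.set_index("variant_id")
    rows, audit = [], []
    for rec in exposure.df.itertuples(index=False):
        vid = rec.variant_id
        if vid not in out.index:
            audit.append((vid, "dropped_missing"))
            continue
        o = out.loc[vid]
        action, flip = _align_one(
            rec.effect_allele, rec.other_allele,
            o["effect_allele"], o["other_allele"],
            rec.eaf, o["eaf"], palindrome_window,
        )
        audit.append((vid, action))
        if action.startswith("dropped"):
            continue
        beta_y = -o["beta"] if flip else o["beta"]
        rows.append(
            {
                "variant_id": vid,
                "chrom": rec.chrom,
                "pos": rec.pos,
                "eaf": rec.eaf,
                "beta_x": rec.beta,
                "se_x": rec.se,
                "pval_x": rec.pval,
                "beta_y": beta_y,
                "se_y": o["se"],
                "pval_y": o["pval"],
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["variant_id", "chrom", "pos", "eaf", "beta_x", "se_x", "pval_x",
                 "beta_y", "se_y", "pval_y"],
    )
    audit_df = pd.DataFrame(audit, columns=["variant_id", "alignment_action"])
    return HarmonizedSet(df=df, audit=audit_df,
                         n_x=exposure.sample_size, n_y=outcome.sample_size)


def harmonize_multi(
    exposure: SummaryStatSet,
    extra_exposures: dict[str, SummaryStatSet],
    outcome: SummaryStatSet,
    palindrome_window: tuple[float, float] = PALINDROME_AMBIGUITY_WINDOW,
) -> HarmonizedSet:
    """Joint harmonization for multivariable MR.

    Every additional exposure and the outcome are aligned to the primary
    exposure's effect allele; a variant is retained only when present and
    alignable in all tables (the no-proxy rule applies to every trait).
    Adds ``beta_<name>, se_<name>`` columns per extra exposure.
    """
    h = harmonize_pair(exposure, outcome, palindrome_window)
    df = h.df
    audit = h.audit.set_index("variant_id")
    for name, med in extra_exposures.items():
        hm = harmonize_pair(exposure, med, palindrome_window)
        sub = hm.df[["variant_id", "beta_y", "se_y"]].rename(
            columns={"beta_y": f"beta_{name}", "se_y": f"se_{name}"}
        )
        df = df.merge(sub, on="variant_id", how="inner")
        dropped = hm.audit.loc[
            hm.audit["alignment_action"].str.startswith("dropped"), "variant_id"
        ]
        med_audit = hm.audit.set_index("variant_id")
        for vid in dropped:
            if not audit.loc[vid, "alignment_action"].startswith("dropped"):
                audit.loc[vid, "alignment_action"] = med_audit.loc[vid, "alignment_action"]
    return HarmonizedSet(
        df=df.reset_index(drop=True),
        audit=audit.reset_index(),
        n_x=h.n_x,
        n_y=h.n_y,
    )
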