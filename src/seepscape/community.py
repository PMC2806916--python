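"""Clone-library composition summaries and the joint activity table.

Count tables are tidy DataFrames (sample_id, taxon_id, count); a group map
(taxon_id, group, role) assigns each taxon to a phylogenetic group and an
ecological role: SRB (putative sulfate reducers), ANME (putative anaerobic
methane cyclers), or other. The activity summary joins, per core and depth
layer, the role percentages with diffusive fluxes and mRNA detections the
way the transect figure encodes them: sulfate flux as absolute value,
methane flux times ten, marker-gene presence as 100/0.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import JoinError, MappingError, ValidationError
from .fluxes import FluxResult

ROLES = ("SRB", "ANME", "other")

COUNT_COLUMNS = ["sample_id", "taxon_id", "count"]
GROUPMAP_COLUMNS = ["taxon_id", "group", "role"]


def validate_count_table(counts: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COUNT_COLUMNS if c not in counts.columns]
    if missing:
        raise ValidationError(f"count table missing column(s): {missing}")
    df = counts[COUNT_COLUMNS].copy()
    if (df["count"] < 0).any() or (df["count"] != df["count"].astype(int)).any():
        raise ValidationError("counts must be non-negative integers")
    df["count"] = df["count"].astype(int)
    totals = df.groupby("sample_id")["count"].sum()
    empty = totals[totals == 0].index.tolist()
    if empty:
        raise ValidationError(f"samples with no positive counts: {empty}")
    return df


def validate_group_map(groups: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in GROUPMAP_COLUMNS if c not in groups.columns]
    if missing:
        raise ValidationError(f"group map missing column(s): {missing}")
    df = groups[GROUPMAP_COLUMNS].copy()
    if df["taxon_id"].duplicated().any():
        dups = df.loc[df["taxon_id"].duplicated(), "taxon_id"].tolist()
        raise ValidationError(f"duplicate taxon_id in group map: {dups}")
    bad = set(df["role"]) - set(ROLES)
    if bad:
        raise ValidationError(f"roles outside {ROLES}: {sorted(bad)}")
    return df


@dataclass(frozen=True)
class RoleFractions:
    """Per-sample composition percentages for one domain's libraries."""

    domain: str
    by_group: pd.DataFrame = field(repr=False)  # sample_id, group, role, count, pct
    by_role: pd.DataFrame = field(repr=False)  # sample_id x role percentages

    def pct(self, sample_id: str, role: str) -> float:
        return float(self.by_role.loc[sample_id, role])


def group_fractions(counts: pd.DataFrame, groups: pd.DataFrame, domain: str) -> RoleFractions:
    """Percentage of clones per phylogenetic group and per ecological role.

    Every taxon in the count table must be mapped; role percentages sum to
    100 within each sample.
    """
    if domain not in ("bacteria", "archaea"):
        raise ValidationError("domain must be 'bacteria' or 'archaea'")
    counts = validate_count_table(counts)
    groups = validate_group_map(groups)
    unmapped = set(counts["taxon_id"]) - set(groups["taxon_id"])
    if unmapped:
        raise MappingError(f"taxa missing from group map: {sorted(unmapped)}")
    merged = counts.merge(groups, on="taxon_id")
    by_group = (
        merged.groupby(["sample_id", "group", "role"], as_index=False)["count"].sum()
    )
    totals = by_group.groupby("sample_id")["count"].transform("sum")
    by_group["pct"] = 100.0 * by_group["count"] / totals
    by_role = (
        by_group.pivot_table(index="sample_id", columns="role", values="pct", aggfunc="sum")
        .reindex(columns=ROLES, fill_value=0.0)
        .fillna(0.0)
    )
    return RoleFractions(domain, by_group, by_role)


@dataclass(frozen=True)
class ActivityRow:
    """One core x depth-layer row of the joint geochemistry/community table."""

    sample_id: str
    layer: str  # surface | deep
    pct_SRB_clones: float
    pct_ANME_clones: float
    dsrAB_present: int  # 100 or 0
    mcrA_present: int
    abs_sulfate_flux: float  # mmol m^-2 d^-1
    methane_flux_x10: float | None
    methane_flux_note: str = ""


def build_activity_summary(
    bacterial: RoleFractions,
    archaeal: RoleFractions,
    mrna_flags: dict[str, dict[str, bool]],
    sulfate_fluxes: dict[str, FluxResult],
    methane_fluxes: dict[str, FluxResult | None],
    layer: str,
    methane_missing_reason: str = "methane above atmospheric saturation",
) -> list[ActivityRow]:
    """Join role fractions, marker-gene detections, and fluxes per sample.

    A missing methane flux (None) is carried through with its reason; every
    sample must appear in all other inputs.
    """
    samples = list(sulfate_fluxes)
    for name, keys in (
        ("bacterial fractions", set(bacterial.by_role.index)),
        ("archaeal fractions", set(archaeal.by_role.index)),
        ("mRNA flags", set(mrna_flags)),
        ("methane fluxes", set(methane_fluxes)),
    ):
        missing = set(samples) - keys
        if missing:
            raise JoinError(f"samples missing from {name}: {sorted(missing)}")
    rows = []
    for s in samples:
        mf = methane_fluxes[s]
        rows.append(
            ActivityRow(
                sample_id=s,
                layer=layer,
                pct_SRB_clones=bacterial.pct(s, "SRB"),
                pct_ANME_clones=archaeal.pct(s, "ANME"),
                dsrAB_present=100 if mrna_flags[s].get("dsrAB") else 0,
                mcrA_present=100 if mrna_flags[s].get("mcrA") else 0,
                abs_sulfate_flux=abs(sulfate_fluxes[s].flux),
                methane_flux_x10=None if mf is None else 10.0 * mf.flux,
                methane_flux_note="" if mf is not None else methane_missing_reason,
            )
        )
    return rows


def summary_frame(rows: list[ActivityRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows])


@dataclass(frozen=True)
class ConcordanceResult:
    layer: str
    pairing: str  # e.g. "abs_sulfate_flux ~ pct_SRB_clones"
    concordant_fraction: float | None  # None when every pair is tied/missing
    n_pairs_used: int
    ties: list[tuple[str, str]]


def concordance_check(rows: list[ActivityRow]) -> list[ConcordanceResult]:
    """Ordinal agreement between flux magnitude and community fractions.

    For each depth layer, enumerates all core pairs and reports the fraction
    of pairs where the ordering of |sulfate flux| matches the ordering of
    the SRB clone percentage, and likewise methane flux vs. ANME percentage.
    Tied pairs (in either variable) are excluded from the fraction and
    listed explicitly; samples with missing methane flux are skipped for the
    methane pairing.
    """
    results = []
    for layer in sorted({r.layer for r in rows}):
        sub = [r for r in rows if r.layer == layer]
        if len(sub) < 2:
            raise ValidationError(f"concordance needs >= 2 samples in layer {layer!r}")
        results.append(_pair_fraction(sub, layer, "abs_sulfate_flux", "pct_SRB_clones"))
        results.append(_pair_fraction(sub, layer, "methane_flux_x10", "pct_ANME_clones"))
    return results


def _pair_fraction(rows, layer, flux_attr, pct_attr) -> ConcordanceResult:
    usable = [r for r in rows if getattr(r, flux_attr) is not None]
    conc = used = 0
    ties: list[tuple[str, str]] = []
    for a, b in itertools.combinations(usable, 2):
        df = getattr(a, flux_attr) - getattr(b, flux_attr)
        dp = getattr(a, pct_attr) - getattr(b, pct_attr)
        if df == 0 or dp == 0:
            ties.append((a.sample_id, b.sample_id))
            continue
        used += 1
        if math.copysign(1, df) == math.copysign(1, dp):
            conc += 1
    frac = conc / used if used else None
    return ConcordanceResult(layer, f"{flux_attr} ~ {pct_attr}", frac, used, ties)
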