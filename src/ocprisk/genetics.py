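"""Genotype-table statistics and gene-cluster susceptibility scoring.

The panel covers 21 markers in 14 genes grouped into three functional
clusters — DNA repair (XRCC1, XRCC3, XPD), xenobiotic detoxification
(CYP1A1, CYP2B6, CYP2D6, CYP2C19, GSTT1, GSTM1, GSTP1) and antioxidant
defence (SOD1, NFE2L3, GPX4, GCLM, GCLC).  Nineteen markers are
codominant single-nucleotide variants genotyped as risk-allele dosage
0/1/2; GSTT1 and GSTM1 are whole-gene deletions for which only the
homozygous-null phenotype is assay-observable, coded "+" (at least one
functional copy) or "-" (null/null).

Per-variant statistics: allele frequencies, Hardy–Weinberg equilibrium
Pearson chi-square (df defaults to 2), and per-sample call-rate QC.
Per-individual statistics: the 0-1 cluster susceptibility scores that
enter the risk regression as predictors X5-X7.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd
from scipy import stats

__all__ = [
    "Cluster",
    "VariantDefinition",
    "GenotypeCounts",
    "HWEResult",
    "ClusterScores",
    "DEFAULT_PANEL",
    "CALL_RATE_THRESHOLD",
    "allele_freq_codominant",
    "allele_freq_dominant",
    "hwe_test",
    "sample_qc",
    "genotype_score",
    "cluster_scores",
    "load_panel",
    "load_reference_genotype_counts",
    "genotype_summary",
    "summarize_cohort_genotypes",
]

Cluster = Literal["repair", "detox", "antioxidant"]
MarkerModel = Literal["codominant", "dominant_deletion"]

#: samples with a genotyping call rate below this fraction are excluded
CALL_RATE_THRESHOLD = 0.98


@dataclass(frozen=True)
class VariantDefinition:
    """One marker of the susceptibility panel."""

    rsid: str
    gene: str
    cluster: Cluster
    marker_model: MarkerModel = "codominant"
    #: label of the non-functional (risk) allele; informational only
    risk_allele: str = "B"


@dataclass(frozen=True)
class GenotypeCounts:
    """Observed genotype counts for one variant.

    Codominant markers use ``n_aa`` (ancestral hom), ``n_ab`` (het),
    ``n_bb`` (risk hom).  Deletion markers use ``n_positive`` (+/+ or
    +/-) and ``n_null`` (-/-).
    """

    n_aa: int = 0
    n_ab: int = 0
    n_bb: int = 0
    n_positive: int = 0
    n_null: int = 0

    @property
    def n_codominant(self) -> int:
        return self.n_aa + self.n_ab + self.n_bb

    @property
    def n_dominant(self) -> int:
        return self.n_positive + self.n_null


@dataclass(frozen=True)
class HWEResult:
    chi2: float
    df: int
    p_value: float
    p_a: float
    p_b: float


@dataclass(frozen=True)
class ClusterScores:
    repair: float
    detox: float
    antioxidant: float
    missing_fraction: float = 0.0

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.repair, self.detox, self.antioxidant)


# The default 21-marker panel: 4 repair SNVs, 9 detoxification markers
# (including the two deletion polymorphisms), 8 antioxidant SNVs.  The
# third GSTP1 intronic marker (rs1871042) is kept with its GSTP1
# assignment even though it duplicates the gene.
DEFAULT_PANEL: tuple[VariantDefinition, ...] = (
    VariantDefinition("rs861539", "XRCC3", "repair"),
    VariantDefinition("rs1799782", "XRCC1", "repair"),
    VariantDefinition("rs25487", "XRCC1", "repair"),
    VariantDefinition("rs13181", "XPD", "repair"),
    VariantDefinition("rs17861084", "CYP1A1", "detox"),
    VariantDefinition("rs8192718", "CYP2B6", "detox"),
    VariantDefinition("rs186133763", "CYP2D6", "detox"),
    VariantDefinition("rs11592737", "CYP2C19", "detox"),
    VariantDefinition("rs1601993659", "GSTT1", "detox", "dominant_deletion", "-"),
    VariantDefinition("rs1183423000", "GSTM1", "detox", "dominant_deletion", "-"),
    VariantDefinition("rs1138272", "GSTP1", "detox"),
    VariantDefinition("rs1695", "GSTP1", "detox"),
    VariantDefinition("rs1871042", "GSTP1", "detox"),
    VariantDefinition("rs138002121", "SOD1", "antioxidant"),
    VariantDefinition("rs1041740", "SOD1", "antioxidant"),
    VariantDefinition("rs2237329", "NFE2L3", "antioxidant"),
    VariantDefinition("rs713041", "GPX4", "antioxidant"),
    VariantDefinition("rs41303970", "GCLM", "antioxidant"),
    VariantDefinition("rs12524550", "GCLC", "antioxidant"),
    VariantDefinition("rs3799694", "GCLC", "antioxidant"),
    VariantDefinition("rs524553", "GCLC", "antioxidant"),
)


def allele_freq_codominant(counts: GenotypeCounts) -> tuple[float, float]:
    """Allele frequencies (pA, pB) by allele counting.

    pA = (2·nAA + nAB) / 2n with A the ancestral and B the risk allele.
    """
    n = counts.n_codominant
    if n <= 0:
        raise ValueError("no genotyped individuals: total codominant count is 0")
    p_a = (2 * counts.n_aa + counts.n_ab) / (2 * n)
    return p_a, 1.0 - p_a


def allele_freq_dominant(n_positive: int, n_null: int) -> tuple[float, float]:
    """Allele frequencies (p+, p-) for a deletion marker.

    Only the null/null phenotype is observable, so the null-allele
    frequency is estimated as sqrt(null fraction) assuming
    Hardy–Weinberg proportions for a recessive null.
    """
    n = n_positive + n_null
    if n <= 0:
        raise ValueError("no genotyped individuals: total dominant-marker count is 0")
    p_minus = math.sqrt(n_null / n)
    return 1.0 - p_minus, p_minus


def hwe_test(counts: GenotypeCounts, df: int = 2) -> HWEResult:
    """Pearson chi-square test of Hardy–Weinberg proportions.

    Expected counts are n·p², 2npq, n·q² from the observed allele
    frequencies; no continuity correction.  ``df`` defaults to 2 (the
    convention used with the bundled reference counts); the textbook
    df=1 is available by argument.
    """
    n = counts.n_codominant
    p_a, p_b = allele_freq_codominant(counts)
    observed = (counts.n_aa, counts.n_ab, counts.n_bb)
    expected = (n * p_a * p_a, 2 * n * p_a * p_b, n * p_b * p_b)
    chi2 = 0.0
    for obs, exp in zip(observed, expected):
        if exp == 0.0:
            if obs:
                warnings.warn(
                    "expected genotype count of 0 with nonzero observed count; "
                    "chi-square is infinite",
                    RuntimeWarning,
                    stacklevel=2,
                )
                chi2 = math.inf
                break
            continue
        chi2 += (obs - exp) ** 2 / exp
    p_value = float(stats.chi2.sf(chi2, df)) if math.isfinite(chi2) else 0.0
    return HWEResult(chi2=chi2, df=df, p_value=p_value, p_a=p_a, p_b=p_b)


def sample_qc(call_rate: float) -> bool:
    """True (keep) iff the sample call rate is at least 98%.

    The exclusion rule is strict: exactly 0.98 is kept.
    """
    if not 0.0 <= call_rate <= 1.0:
        raise ValueError(f"call rate must be in [0, 1], got {call_rate}")
    return call_rate >= CALL_RATE_THRESHOLD


def genotype_score(
    genotype: int | str,
    variant: VariantDefinition,
    coding: Literal["dominant", "additive"] = "dominant",
) -> float:
    """0-1 risk score of one genotype.

    0 means full functionality of the encoded protein; 1 means a
    non-functional (risk) allele is present.  Under the default
    dominant coding a heterozygote scores 1; the additive alternative
    scores risk-allele dosage / 2.  Deletion markers score 1 only for
    the null/null phenotype, since "+/-" cannot be distinguished from
    "+/+" by the assay.
    """
    if variant.marker_model == "dominant_deletion":
        if genotype in ("+", "+/+", "+/-"):
            return 0.0
        if genotype in ("-", "-/-"):
            return 1.0
        raise ValueError(
            f"unknown deletion-marker genotype {genotype!r} for {variant.rsid}"
        )
    if genotype not in (0, 1, 2):
        raise ValueError(
            f"unknown codominant genotype {genotype!r} for {variant.rsid}; "
            "expected risk-allele dosage 0, 1 or 2"
        )
    if coding == "additive":
        return genotype / 2.0
    return 1.0 if genotype >= 1 else 0.0


def cluster_scores(
    genotypes: Mapping[str, int | str | None],
    panel: Sequence[VariantDefinition] = DEFAULT_PANEL,
    coding: Literal["dominant", "additive"] = "dominant",
) -> ClusterScores:
    """Per-cluster mean genotype score for one individual.

    Missing genotypes (``None`` or absent rsID) are dropped from the
    cluster mean; a cluster with no genotyped marker at all is an
    error.  Scores are permutation-invariant within a cluster and lie
    in [0, 1].
    """
    sums: dict[str, float] = {"repair": 0.0, "detox": 0.0, "antioxidant": 0.0}
    counts: dict[str, int] = {"repair": 0, "detox": 0, "antioxidant": 0}
    missing = 0
    for variant in panel:
        value = genotypes.get(variant.rsid)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            missing += 1
            continue
        sums[variant.cluster] += genotype_score(value, variant, coding)
        counts[variant.cluster] += 1
    for cluster, k in counts.items():
        if k == 0:
            raise ValueError(f"all {cluster}-cluster variants are missing")
    return ClusterScores(
        repair=sums["repair"] / counts["repair"],
        detox=sums["detox"] / counts["detox"],
        antioxidant=sums["antioxidant"] / counts["antioxidant"],
        missing_fraction=missing / len(panel),
    )


# ---------------------------------------------------------------------------
# Panel / reference-count I/O and cohort summaries


def load_panel(path=None) -> tuple[VariantDefinition, ...]:
    """Load a variant panel from CSV (rsid,gene,cluster,marker_model,risk_allele).

    With no path the built-in 21-marker panel is returned.
    """
    if path is None:
        return DEFAULT_PANEL
    frame = pd.read_csv(path, dtype=str)
    required = {"rsid", "gene", "cluster", "marker_model"}
    if not required.issubset(frame.columns):
        raise ValueError(f"panel file must have columns {sorted(required)}")
    return tuple(
        VariantDefinition(
            rsid=row.rsid,
            gene=row.gene,
            cluster=row.cluster,
            marker_model=row.marker_model,
            risk_allele=getattr(row, "risk_allele", "B") or "B",
        )
        for row in frame.itertuples(index=False)
    )


def load_reference_genotype_counts() -> dict[str, GenotypeCounts]:
    """Bundled per-variant genotype counts of the surveyed cohort."""
    with resources.files("ocprisk.data").joinpath("genotype_counts.csv").open() as fh:
        frame = pd.read_csv(fh, na_values=["NA"])
    out: dict[str, GenotypeCounts] = {}
    for row in frame.itertuples(index=False):
        if pd.isna(row.n_AA):
            out[row.rsid] = GenotypeCounts(
                n_positive=int(row.n_positive), n_null=int(row.n_null)
            )
        else:
            out[row.rsid] = GenotypeCounts(
                n_aa=int(row.n_AA), n_ab=int(row.n_AB), n_bb=int(row.n_BB)
            )
    return out


def genotype_summary(
    counts_by_rsid: Mapping[str, GenotypeCounts],
    panel: Sequence[VariantDefinition] = DEFAULT_PANEL,
    df: int = 2,
) -> pd.DataFrame:
    """Per-variant summary: counts, allele frequencies, HWE chi2 and p.

    Codominant markers get the full HWE test; deletion markers report
    the sqrt-estimator allele frequencies and, separately, the raw
    null-phenotype fraction (``null_phenotype_freq``), which is the
    only model-free quantity the assay supports.
    """
    rows = []
    for variant in panel:
        counts = counts_by_rsid.get(variant.rsid)
        if counts is None:
            continue
        row: dict[str, object] = {
            "rsid": variant.rsid,
            "gene": variant.gene,
            "cluster": variant.cluster,
            "marker_model": variant.marker_model,
        }
        if variant.marker_model == "codominant":
            result = hwe_test(counts, df=df)
            row.update(
                n_AA=counts.n_aa,
                n_AB=counts.n_ab,
                n_BB=counts.n_bb,
                freq_A=result.p_a,
                freq_B=result.p_b,
                chi2=result.chi2,
                p_value=result.p_value,
            )
        else:
            p_plus, p_minus = allele_freq_dominant(counts.n_positive, counts.n_null)
            row.update(
                n_positive=counts.n_positive,
                n_null=counts.n_null,
                freq_A=p_plus,
                freq_B=p_minus,
                null_phenotype_freq=counts.n_null / counts.n_dominant,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_cohort_genotypes(
    cohort: pd.DataFrame,
    panel: Sequence[VariantDefinition] = DEFAULT_PANEL,
    df: int = 2,
) -> pd.DataFrame:
    """Tabulate genotype counts from per-individual calls and summarize.

    ``cohort`` holds one column per rsID with values 0/1/2 (codominant)
    or "+"/"-" (deletion markers); missing calls are NA.
    """
    counts: dict[str, GenotypeCounts] = {}
    for variant in panel:
        if variant.rsid not in cohort.columns:
            continue
        column = cohort[variant.rsid].dropna()
        if variant.marker_model == "codominant":
            values = column.astype(int)
            counts[variant.rsid] = GenotypeCounts(
                n_aa=int((values == 0).sum()),
                n_ab=int((values == 1).sum()),
                n_bb=int((values == 2).sum()),
            )
        else:
            counts[variant.rsid] = GenotypeCounts(
                n_positive=int((column == "+").sum()),
                n_null=int((column == "-").sum()),
            )
    return genotype_summary(counts, panel, df=df)


def individual_cluster_scores(
    cohort: pd.DataFrame,
    panel: Sequence[VariantDefinition] = DEFAULT_PANEL,
    coding: Literal["dominant", "additive"] = "dominant",
) -> pd.DataFrame:
    """Cluster scores (X5/X6/X7) for every row of a cohort table."""
    records = []
    for _, row in cohort.iterrows():
        genotypes = {
            v.rsid: (None if pd.isna(row.get(v.rsid)) else row[v.rsid]) for v in panel
        }
        scores = cluster_scores(genotypes, panel, coding)
        records.append(
            {
                "repair_score": scores.repair,
                "detox_score": scores.detox,
                "antioxidant_score": scores.antioxidant,
                "missing_fraction": scores.missing_fraction,
            }
        )
    return pd.DataFrame(records, index=cohort.index)
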