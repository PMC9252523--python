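"""Core value types shared across the pipeline.

Every type validates its invariants at construction time: no silently
invalid object can exist downstream of a constructor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

COHORT_LABELS = ("ref_normal", "adj_normal", "tumor")
SEX_LABELS = ("male", "female", "unknown")
_BASES = frozenset("ACGT")


class ValidationError(ValueError):
    """An object violates a type invariant."""


class FormatError(ValueError):
    """An external file violates its declared format."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class GeneSet:
    """A named, de-duplicated collection of gene identifiers."""

    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(g.strip() for g in self.genes))
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
        _check_unique(self.genes, f"gene (set {self.name!r})")

    @classmethod
    def from_genes(cls, name: str, genes: Sequence[str], description: str = "") -> "GeneSet":
        """Build a set, collapsing duplicates while preserving first-seen order."""
        seen: dict[str, None] = {}
        for g in genes:
            seen.setdefault(g.strip(), None)
        return cls(name=name, genes=tuple(seen), description=description)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


@dataclass
class ExpressionCohort:
    """Gene x sample non-negative expression matrix with per-sample metadata.

    ``values`` holds linear-scale (TPM-like) expression, genes in rows,
    samples in columns. ``cohort`` and ``sex`` are per-sample labels drawn
    from closed vocabularies.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray
    cohort: tuple[str, ...]
    sex: tuple[str, ...]

    def __post_init__(self) -> None:
        self.gene_ids = tuple(str(g).strip() for g in self.gene_ids)
        self.sample_ids = tuple(str(s).strip() for s in self.sample_ids)
        self.cohort = tuple(self.cohort)
        self.sex = tuple(self.sex)
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.cohort) != len(self.sample_ids):
            raise ValidationError("cohort labels do not match sample count")
        if len(self.sex) != len(self.sample_ids):
            raise ValidationError("sex labels do not match sample count")
        for c in self.cohort:
            if c not in COHORT_LABELS:
                raise ValidationError(f"unknown cohort label {c!r}")
        for s in self.sex:
            if s not in SEX_LABELS:
                raise ValidationError(f"unknown sex label {s!r}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression matrix contains non-finite values")
        if np.any(self.values < 0):
            raise ValidationError("expression matrix contains negative values")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_values(self, gene: str) -> np.ndarray:
        """Expression vector (over samples) for one gene."""
        try:
            return self.values[self._gene_index[gene]]
        except KeyError:
            raise KeyError(f"gene {gene!r} not present in cohort") from None

    def has_gene(self, gene: str) -> bool:
        return gene in self._gene_index

    def subset_samples(self, mask: np.ndarray) -> "ExpressionCohort":
        mask = np.asarray(mask, dtype=bool)
        idx = np.flatnonzero(mask)
        return ExpressionCohort(
            gene_ids=self.gene_ids,
            sample_ids=tuple(self.sample_ids[i] for i in idx),
            values=self.values[:, idx],
            cohort=tuple(self.cohort[i] for i in idx),
            sex=tuple(self.sex[i] for i in idx),
        )

    def select_cohort(self, label: str) -> "ExpressionCohort":
        if label not in COHORT_LABELS:
            raise ValidationError(f"unknown cohort label {label!r}")
        return self.subset_samples(np.array([c == label for c in self.cohort]))

    def with_sex(self, sex: Sequence[str]) -> "ExpressionCohort":
        return replace(self, sex=tuple(sex))

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "cohort": self.cohort, "sex": self.sex}
        )


@dataclass
class SurvivalTable:
    """Per-sample follow-up time (days), event indicator, and covariates."""

    df: pd.DataFrame = field(repr=False)

    REQUIRED = ("sample_id", "time_days", "event", "sex")

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValidationError(f"survival table missing required column {col!r}")
        df["sample_id"] = df["sample_id"].astype(str)
        df["time_days"] = pd.to_numeric(df["time_days"])
        df["event"] = pd.to_numeric(df["event"])
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicate sample id in survival table: {dup!r}")
        if not np.all(df["time_days"].to_numpy() > 0):
            raise ValidationError("survival times must be > 0")
        if not df["event"].isin([0, 1]).all():
            bad = df.loc[~df["event"].isin([0, 1]), "event"].iloc[0]
            raise ValidationError(f"event indicator must be 0 or 1, got {bad!r}")
        for s in df["sex"]:
            if s not in SEX_LABELS:
                raise ValidationError(f"unknown sex label {s!r} in survival table")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.df["sample_id"])

    @property
    def time(self) -> np.ndarray:
        return self.df["time_days"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.df["event"].to_numpy(dtype=int)

    def restrict(self, sample_ids: Sequence[str]) -> "SurvivalTable":
        keep = self.df["sample_id"].isin(set(sample_ids))
        return SurvivalTable(self.df.loc[keep])


@dataclass
class GwasSummaryTable:
    """Per-SNP summary statistics for one GWAS."""

    df: pd.DataFrame = field(repr=False)

    REQUIRED = ("snp_id", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n")

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValidationError(f"GWAS table missing required column {col!r}")
        df["snp_id"] = df["snp_id"].astype(str)
        for col in ("eaf", "beta", "se", "pval", "n"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
        if df["snp_id"].duplicated().any():
            dup = df.loc[df["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise ValidationError(f"duplicate SNP id: {dup!r}")
        for col in ("effect_allele", "other_allele"):
            df[col] = df[col].astype(str).str.strip().str.upper()
        bad = self._invalid_rows(df)
        if bad.any():
            raise ValidationError(
                f"{int(bad.sum())} GWAS rows violate invariants "
                f"(first offender: {df.loc[bad, 'snp_id'].iloc[0]!r}); "
                "use GwasSummaryTable.clean() to drop them"
            )
        self.df = df.reset_index(drop=True)

    @staticmethod
    def _invalid_rows(df: pd.DataFrame) -> pd.Series:
        ok_alleles = df["effect_allele"].isin(_BASES) & df["other_allele"].isin(_BASES)
        ok_alleles &= df["effect_allele"] != df["other_allele"]
        ok_se = df["se"].notna() & (df["se"] > 0)
        ok_beta = df["beta"].notna() & np.isfinite(df["beta"])
        ok_p = df["pval"].isna() | ((df["pval"] > 0) & (df["pval"] <= 1))
        ok_eaf = df["eaf"].isna() | ((df["eaf"] > 0) & (df["eaf"] < 1))
        ok_n = df["n"].isna() | (df["n"] > 0)
        return ~(ok_alleles & ok_se & ok_beta & ok_p & ok_eaf & ok_n)

    @classmethod
    def clean(cls, df: pd.DataFrame) -> tuple["GwasSummaryTable", int]:
        """Validate ``df``, dropping invalid rows; returns (table, n_dropped)."""
        work = df.copy()
        for col in cls.REQUIRED:
            if col not in work.columns:
                raise ValidationError(f"GWAS table missing required column {col!r}")
        for col in ("eaf", "beta", "se", "pval", "n"):
            work[col] = pd.to_numeric(work[col], errors="coerce")
        for col in ("effect_allele", "other_allele"):
            work[col] = work[col].astype(str).str.strip().str.upper()
        work = work.drop_duplicates(subset="snp_id", keep="first")
        bad = cls._invalid_rows(work)
        n_dropped = int(bad.sum()) + (len(df) - len(work))
        return cls(work.loc[~bad]), n_dropped

    def __len__(self) -> int:
        return len(self.df)
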