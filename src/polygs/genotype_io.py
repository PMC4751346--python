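"""Genotype, genetic-map and phenotype I/O plus structure diagnostics.

Genotypes are biallelic SNP codes in {-1, 0, +1} (minus/hetero/plus
homozygote), the common currency of every downstream module.  Missing
calls are carried as NaN and must be mean-imputed before LD or model
fitting.  The on-disk formats are small delimited text tables; a PLINK
additive-coded dialect (0/1/2) and PLINK ``.map`` files are accepted for
interoperability.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "CodingError",
    "ValidationError",
    "GenotypeMatrix",
    "MarkerMap",
    "read_genotypes",
    "write_genotypes",
    "read_map",
    "write_map",
    "read_phenotypes",
    "write_phenotypes",
    "impute_missing",
    "allele_frequency",
    "pca_scores",
]

#: tokens treated as a missing genotype call on disk
MISSING_TOKENS = {"", "NA", "NaN", "nan"}

_ALLOWED = {-1.0, 0.0, 1.0}


class CodingError(ValueError):
    """A genotype value outside the allowed code set, located by row/column."""


class ValidationError(ValueError):
    """Structural problem: duplicated ids, shape mismatch, bad labels."""


@dataclass
class GenotypeMatrix:
    """Individuals x markers matrix of additive SNP codes.

    ``codes`` is a float array; NaN marks a missing call.  After
    :func:`impute_missing` entries may be fractional (marker means), so
    the strict {-1,0,1} check applies only to non-imputed matrices via
    :meth:`validate_codes`.
    """

    individual_ids: list[str]
    generation_labels: list[str]
    marker_ids: list[str]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=float)
        if self.codes.ndim != 2:
            raise ValidationError("codes must be a 2-D array")
        n, m = self.codes.shape
        if len(self.individual_ids) != n:
            raise ValidationError(
                f"{len(self.individual_ids)} individual ids for {n} rows"
            )
        if len(self.generation_labels) != n:
            raise ValidationError(
                f"{len(self.generation_labels)} generation labels for {n} rows"
            )
        if len(self.marker_ids) != m:
            raise ValidationError(f"{len(self.marker_ids)} marker ids for {m} columns")
        if len(set(self.individual_ids)) != n:
            raise ValidationError("duplicate individual ids")
        if len(set(self.marker_ids)) != m:
            raise ValidationError("duplicate marker ids")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    def validate_codes(self) -> None:
        """Check every non-missing entry is exactly -1, 0 or +1."""
        bad = ~(np.isnan(self.codes) | np.isin(self.codes, [-1.0, 0.0, 1.0]))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise CodingError(
                f"invalid genotype code {self.codes[i, j]!r} for individual "
                f"{self.individual_ids[i]!r}, marker {self.marker_ids[j]!r}"
            )

    def has_missing(self) -> bool:
        return bool(np.isnan(self.codes).any())

    def select_individuals(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            [self.individual_ids[i] for i in idx],
            [self.generation_labels[i] for i in idx],
            list(self.marker_ids),
            self.codes[idx],
        )

    def select_generations(self, labels) -> "GenotypeMatrix":
        wanted = set(labels)
        mask = np.array([g in wanted for g in self.generation_labels])
        return self.select_individuals(mask)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.codes, columns=self.marker_ids)
        df.insert(0, "generation", self.generation_labels)
        df.insert(0, "individual_id", self.individual_ids)
        return df


@dataclass
class MarkerMap:
    """Genetic map: marker -> (chromosome, position in centimorgans)."""

    marker_ids: list[str]
    chromosomes: np.ndarray
    positions_cm: np.ndarray

    def __post_init__(self) -> None:
        self.chromosomes = np.asarray(self.chromosomes, dtype=int)
        self.positions_cm = np.asarray(self.positions_cm, dtype=float)
        n = len(self.marker_ids)
        if len(self.chromosomes) != n or len(self.positions_cm) != n:
            raise ValidationError("map columns have unequal lengths")
        if len(set(self.marker_ids)) != n:
            raise ValidationError("duplicate marker ids in map")
        if (self.positions_cm < 0).any():
            raise ValidationError("negative map position")

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def chromosome_markers(self, chromosome: int) -> pd.DataFrame:
        """Markers on one chromosome sorted by position."""
        df = self.to_frame()
        sub = df[df["chromosome"] == chromosome].sort_values(
            ["position_cm", "marker_id"], kind="stable"
        )
        return sub.reset_index(drop=True)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_ids,
                "chromosome": self.chromosomes,
                "position_cm": self.positions_cm,
            }
        )


# ---------------------------------------------------------------------------
# readers / writers


def _read_table(path) -> pd.DataFrame:
    # comma/tab autodetection; keep everything as strings for validation
    with open(path, "r") as fh:
        head = fh.readline()
    sep = "\t" if head.count("\t") >= head.count(",") else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_genotypes(path, dialect: str = "native") -> GenotypeMatrix:
    """Read a genotype table.

    ``native``: columns 1-2 are individual id and generation label,
    remaining columns are marker codes in {-1,0,1}.  ``plink_additive``:
    same layout with 0/1/2 codes, mapped to -1/0/+1 by subtracting 1.
    Missing tokens (empty, "NA") become NaN.
    """
    if dialect not in ("native", "plink_additive"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = _read_table(path)
    if df.shape[1] < 3:
        raise ValidationError("genotype table needs id, generation and markers")
    ids = df.iloc[:, 0].tolist()
    gens = df.iloc[:, 1].tolist()
    marker_ids = list(df.columns[2:])
    raw = df.iloc[:, 2:].to_numpy()

    allowed = ["0", "1", "2"] if dialect == "plink_additive" else ["-1", "0", "1"]
    toks = np.char.strip(raw.astype(str))
    missing = np.isin(toks, sorted(MISSING_TOKENS))
    valid = np.isin(toks, allowed)
    bad = ~(missing | valid)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise CodingError(
            f"invalid genotype value {toks[i, j]!r} at individual {ids[i]!r}, "
            f"marker {marker_ids[j]!r} (dialect={dialect})"
        )
    codes = np.full(raw.shape, np.nan)
    codes[valid] = toks[valid].astype(float)
    if dialect == "plink_additive":
        codes = codes - 1.0
    g = GenotypeMatrix(ids, gens, marker_ids, codes)
    g.validate_codes()
    return g


def write_genotypes(g: GenotypeMatrix, path, sep: str = "\t") -> None:
    """Write the native genotype table (missing written as empty)."""
    with open(path, "w") as fh:
        fh.write(sep.join(["individual_id", "generation", *g.marker_ids]) + "\n")
        for i, (iid, gen) in enumerate(zip(g.individual_ids, g.generation_labels)):
            row = [iid, gen]
            for v in g.codes[i]:
                if np.isnan(v):
                    row.append("")
                elif float(v).is_integer():
                    row.append(str(int(v)))
                else:
                    row.append(repr(float(v)))
            fh.write(sep.join(row) + "\n")


def read_map(path) -> MarkerMap:
    """Read a genetic map: native 3-column table or PLINK ``.map``.

    PLINK layout (no header): chromosome, marker_id, genetic position
    (taken as cM), base-pair position.
    """
    path = str(path)
    if path.endswith(".map"):
        df = pd.read_csv(path, sep=None, engine="python", header=None)
        return MarkerMap(
            df.iloc[:, 1].astype(str).tolist(),
            df.iloc[:, 0].to_numpy(int),
            df.iloc[:, 2].to_numpy(float),
        )
    df = _read_table(path)
    need = {"marker_id", "chromosome", "position_cm"}
    if not need.issubset(df.columns):
        raise ValidationError(f"map file must have columns {sorted(need)}")
    return MarkerMap(
        df["marker_id"].tolist(),
        df["chromosome"].astype(int).to_numpy(),
        df["position_cm"].astype(float).to_numpy(),
    )


def write_map(m: MarkerMap, path, sep: str = "\t") -> None:
    m.to_frame().to_csv(path, sep=sep, index=False)


PHENO_COLUMNS = ["individual_id", "generation", "trait", "value"]


def read_phenotypes(path) -> pd.DataFrame:
    """Read a long-format phenotype table.

    Required columns: individual_id, generation, trait, value.  An
    optional ``plot`` column carries plot-level replicates (used by the
    heritability report); without it each row is a family-mean record and
    (individual_id, trait) must be unique.
    """
    df = _read_table(path)
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"phenotype table lacks columns {missing}")
    df["value"] = df["value"].astype(float)
    if not np.isfinite(df["value"]).all():
        raise ValidationError("non-finite phenotype value")
    if "plot" not in df.columns:
        dup = df.duplicated(["individual_id", "trait"])
        if dup.any():
            pair = df.loc[dup.idxmax(), ["individual_id", "trait"]].tolist()
            raise ValidationError(f"duplicate phenotype record for {tuple(pair)}")
    return df


def write_phenotypes(df: pd.DataFrame, path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# operations


def impute_missing(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing calls by the marker mean over non-missing calls.

    Idempotent; a marker with no calls at all is an error.
    """
    if not g.has_missing():
        return g
    codes = g.codes.copy()
    n_obs = (~np.isnan(codes)).sum(axis=0)
    if (n_obs == 0).any():
        j = int(np.argmax(n_obs == 0))
        raise ValidationError(f"marker {g.marker_ids[j]!r} has no non-missing calls")
    col_mean = np.nanmean(codes, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(codes))
    codes[nan_r, nan_c] = col_mean[nan_c]
    return replace(g, codes=codes)


def allele_frequency(g: GenotypeMatrix) -> np.ndarray:
    """Frequency of the +1 allele per marker: (mean code + 1)/2.

    Computed over non-missing entries; with codes counting copies of the
    +1 allele minus one, this equals the direct gamete count over 2n.
    """
    if g.n_individuals == 0 or g.n_markers == 0:
        raise ValidationError("empty genotype matrix")
    return (np.nanmean(g.codes, axis=0) + 1.0) / 2.0


def pca_scores(g: GenotypeMatrix, n_components: int):
    """Principal-component scores of column-centered codes.

    A structure diagnostic: in these breeding populations the first
    component separates the diverged lineages.  Columns are centered but
    not scaled (all codes share a scale).

    Returns ``(scores, explained)``: a DataFrame indexed by individual
    with columns PC1..PCk plus the generation label, and the vector of
    explained-variance fractions (non-increasing, summing to <= 1).
    """
    if g.has_missing():
        raise ValidationError("impute missing genotypes before PCA")
    limit = min(g.n_individuals - 1, g.n_markers)
    if not 1 <= n_components <= limit:
        raise ValueError(f"n_components must be in [1, {limit}], got {n_components}")
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(g.codes)
    df = pd.DataFrame(
        scores,
        index=pd.Index(g.individual_ids, name="individual_id"),
        columns=[f"PC{i + 1}" for i in range(n_components)],
    )
    df["generation"] = g.generation_labels
    return df, pca.explained_variance_ratio_.copy()
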