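"""Genotype/phenotype containers, loading, centering and VanRaden kinship.

Dosage matrices are samples x markers, with any real additive coding
(0/1/2 for outbred diploids, 0/2 for inbred lines).  Centering and the
kinship construction are covariant under affine recoding of a marker, so
downstream quantities do not depend on which allele is counted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypePanel",
    "CenteredDesign",
    "Phenotype",
    "TrainTestSplit",
    "load_genotypes",
    "load_phenotype",
    "center_design",
    "vanraden_kinship",
]


class DataError(ValueError):
    """Malformed input data (duplicate ids, unmatched ids, bad dosage)."""


class DegenerateKinshipError(ValueError):
    """All markers monomorphic in the requested subset."""


@dataclass
class GenotypePanel:
    """A samples x markers allele-dosage matrix with identifiers.

    Parameters
    ----------
    dosages : ndarray of shape (n_samples, n_markers)
        Real-valued allele dosages; no missing values.
    sample_ids, marker_ids : list of str
        Row and column identifiers.
    """

    dosages: np.ndarray
    sample_ids: list[str]
    marker_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise DataError("dosages must be a 2-D samples x markers matrix")
        if np.isnan(self.dosages).any():
            raise DataError("dosage matrix contains missing values")
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise DataError(
                f"{len(self.sample_ids)} sample ids for {n} dosage rows"
            )
        if len(self.marker_ids) != m:
            raise DataError(
                f"{len(self.marker_ids)} marker ids for {m} dosage columns"
            )
        if len(set(self.sample_ids)) != n:
            raise DataError("duplicate sample ids")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def maf(self) -> np.ndarray:
        """Minor-allele frequencies from mean dosage / 2, folded to [0, 0.5]."""
        p = self.dosages.mean(axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def filter_maf(self, threshold: float = 0.0) -> "GenotypePanel":
        """Drop monomorphic markers and markers with MAF below ``threshold``."""
        if not 0.0 <= threshold < 0.5:
            raise ValueError("maf threshold must lie in [0, 0.5)")
        maf = self.maf
        poly = self.dosages.std(axis=0) > 0
        keep = poly & (maf >= threshold)
        dropped = int((~keep).sum())
        if dropped:
            logger.info(
                "MAF filter (threshold %.3g): dropped %d of %d markers",
                threshold, dropped, self.n_markers,
            )
        return GenotypePanel(
            self.dosages[:, keep],
            list(self.sample_ids),
            [mid for mid, k in zip(self.marker_ids, keep) if k],
        )

    def subset(self, idx: np.ndarray) -> "GenotypePanel":
        """Row-subset view (copy) of the panel."""
        idx = np.asarray(idx, dtype=int)
        return GenotypePanel(
            self.dosages[idx],
            [self.sample_ids[i] for i in idx],
            list(self.marker_ids),
        )


@dataclass
class Phenotype:
    """A single trait over the panel's samples."""

    values: np.ndarray
    trait_name: str = "trait"
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.standardized:
            v = self.values.var(ddof=1)
            if abs(v - 1.0) > 1e-10:
                raise ValueError(
                    f"phenotype flagged standardized but variance is {v:.6g}"
                )

    def standardize(self) -> "Phenotype":
        """Rescale to unit sample variance (the optimizer's precondition)."""
        sd = self.values.std(ddof=1)
        if sd == 0:
            raise ValueError("cannot standardize a constant phenotype")
        return Phenotype(self.values / sd, self.trait_name, standardized=True)


@dataclass
class TrainTestSplit:
    """Disjoint train/test index sets into a panel, plus the candidate pool.

    ``candidate_idx`` is the pool a training set may be drawn from during
    optimization; it always contains ``train_idx`` and never overlaps
    ``test_idx``.
    """

    train_idx: np.ndarray
    test_idx: np.ndarray
    candidate_idx: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.train_idx = np.asarray(self.train_idx, dtype=int)
        self.test_idx = np.asarray(self.test_idx, dtype=int)
        if self.candidate_idx is None:
            self.candidate_idx = self.train_idx.copy()
        self.candidate_idx = np.asarray(self.candidate_idx, dtype=int)
        tr, te, ca = map(set, (self.train_idx.tolist(),
                               self.test_idx.tolist(),
                               self.candidate_idx.tolist()))
        if tr & te:
            raise ValueError("train and test indices overlap")
        if not tr <= ca:
            raise ValueError("train indices must be a subset of candidates")
        if ca & te:
            raise ValueError("candidate and test indices overlap")

    def with_train(self, train_idx: np.ndarray) -> "TrainTestSplit":
        return TrainTestSplit(np.asarray(train_idx, dtype=int),
                              self.test_idx, self.candidate_idx)


@dataclass
class CenteredDesign:
    """Training/test dosages column-centered with *training* column means.

    Centering on the training means makes the training design orthogonal
    to the intercept, which the ridge-matrix prediction formula requires,
    and guarantees that prediction never peeks at test-set composition.
    """

    Xc_train: np.ndarray
    Xc_test: np.ndarray
    column_means: np.ndarray


def center_design(panel: GenotypePanel, split: TrainTestSplit,
                  drop_constant: bool = False) -> CenteredDesign:
    """Center training and test dosages by the training column means.

    Parameters
    ----------
    drop_constant : bool
        If True, markers with zero variance within the training rows are
        dropped from both matrices (with a warning) instead of kept as
        all-zero columns.
    """
    if len(split.train_idx) == 0:
        raise ValueError("empty training set")
    X_train = panel.dosages[split.train_idx]
    X_test = panel.dosages[split.test_idx]
    mu = X_train.mean(axis=0)
    Xc_train = X_train - mu
    Xc_test = X_test - mu
    if drop_constant:
        keep = X_train.std(axis=0) > 0
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} markers constant in the "
                "training rows", stacklevel=2)
            Xc_train, Xc_test, mu = Xc_train[:, keep], Xc_test[:, keep], mu[keep]
    return CenteredDesign(Xc_train, Xc_test, mu)


def vanraden_kinship(panel: GenotypePanel, subset: np.ndarray | None = None
                     ) -> np.ndarray:
    """VanRaden genomic relationship matrix on a sample subset.

    K = Zc Zc' / (2 * sum_m p_m (1 - p_m)) with Zc the subset dosages
    centered by twice the subset allele frequencies.  K is symmetric PSD
    but generally singular, which is why prediction goes through the
    ridge matrix H rather than Henderson's equations.
    """
    if subset is None:
        subset = np.arange(panel.n_samples)
    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        raise ValueError("empty subset")
    Z = panel.dosages[subset]
    p = Z.mean(axis=0) / 2.0
    het = p * (1.0 - p)
    denom = 2.0 * het.sum()
    if denom <= 0:
        raise DegenerateKinshipError("all markers monomorphic in subset")
    Zc = Z - 2.0 * p
    return (Zc @ Zc.T) / denom


# ---------------------------------------------------------------------------
# I/O


def _finalize_panel(df: pd.DataFrame, maf_threshold: float) -> GenotypePanel:
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise DataError(f"duplicate sample id(s): {dups}")
    try:
        dos = df.astype(float).to_numpy()
    except ValueError as exc:
        # locate the first offending cell for the error message
        for j, col in enumerate(df.columns):
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                raise DataError(
                    f"non-numeric dosage at sample {df.index[i]!r}, "
                    f"marker {col!r}") from exc
        raise DataError("non-numeric dosage value") from exc
    if np.isnan(dos).any():
        i, j = map(int, np.argwhere(np.isnan(dos))[0])
        raise DataError(
            f"missing dosage at sample {df.index[i]!r}, marker {df.columns[j]!r}")
    panel = GenotypePanel(dos, [str(s) for s in df.index],
                          [str(m) for m in df.columns])
    return panel.filter_maf(maf_threshold)


def load_genotypes(path, format: str = "dosage-csv",
                   maf_threshold: float = 0.0) -> GenotypePanel:
    """Load a dosage matrix from ``dosage-csv`` or PLINK ``plink-raw`` text.

    dosage-csv: header row of marker ids, first column sample id, the rest
    numeric dosages.  plink-raw: whitespace-delimited with header
    FID IID PAT MAT SEX PHENOTYPE then marker columns; only IID and the
    marker columns are consumed.

    Monomorphic markers are always removed; markers with MAF below
    ``maf_threshold`` are removed.
    """
    if format == "dosage-csv":
        df = pd.read_csv(path, index_col=0, dtype=str)
    elif format == "plink-raw":
        df = pd.read_csv(path, sep=r"\s+", dtype=str)
        expected = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
        if list(df.columns[:6]) != expected:
            raise DataError(
                f"plink-raw header must start with {expected}, "
                f"got {list(df.columns[:6])}")
        df = df.set_index("IID").drop(columns=expected[:1] + expected[2:])
    else:
        raise ValueError(f"unknown genotype format {format!r}")
    return _finalize_panel(df, maf_threshold)


def write_genotypes(panel: GenotypePanel, path) -> None:
    """Write a panel as dosage-csv (the load_genotypes round-trip partner)."""
    pd.DataFrame(panel.dosages, index=panel.sample_ids,
                 columns=panel.marker_ids).to_csv(path, index_label="sample_id")


def load_phenotype(path, panel: GenotypePanel) -> Phenotype:
    """Load a two-column (sample_id, value) CSV aligned to ``panel``'s rows."""
    df = pd.read_csv(path, dtype={0: str})
    if df.shape[1] < 2:
        raise DataError("phenotype CSV needs (sample_id, value) columns")
    ids = df.iloc[:, 0].astype(str)
    if ids.duplicated().any():
        raise DataError(
            f"duplicate phenotype id(s): {ids[ids.duplicated()].tolist()}")
    lut = dict(zip(ids, pd.to_numeric(df.iloc[:, 1], errors="raise")))
    missing = [s for s in panel.sample_ids if s not in lut]
    if missing:
        raise DataError(f"phenotype missing for sample id(s): {missing}")
    vals = np.array([lut[s] for s in panel.sample_ids], dtype=float)
    return Phenotype(vals, trait_name=str(df.columns[1]))


def write_phenotype(pheno: Phenotype, sample_ids: list[str], path) -> None:
    pd.DataFrame({"sample_id": sample_ids, pheno.trait_name: pheno.values}
                 ).to_csv(path, index=False)
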