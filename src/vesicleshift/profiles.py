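"""Data model and I/O for protein-level fraction profiles.

A LOPIT-DC experiment quantifies each protein across ~10 differential
centrifugation fractions in several TMT-labelled replicates.  The objects
here hold those profiles, normalise them to per-replicate compositions,
apply contaminant filtering, the additive log-ratio (ALR) transform used by
the downstream two-sample test, PCA projections for spatial maps, and a
margin-based supervised marker classifier with FDR-controlled assignment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from vesicleshift.errors import (
    DegenerateProfileError,
    DimensionError,
    DuplicateIdError,
    SchemaError,
)

logger = logging.getLogger(__name__)

UNKNOWN = "unknown"
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class FractionScheme:
    """Ordered fraction and replicate labels for one condition.

    The fraction order is the GP input coordinate downstream, so it is fixed
    here and must be identical across the conditions being compared.
    """

    fraction_ids: tuple[str, ...]
    replicate_ids: tuple[str, ...]
    condition_id: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "fraction_ids", tuple(self.fraction_ids))
        object.__setattr__(self, "replicate_ids", tuple(self.replicate_ids))
        if len(self.fraction_ids) < 3:
            raise SchemaError(
                "at least 3 fractions are required (the ALR transform needs "
                f">= 2 output dimensions); got {len(self.fraction_ids)}"
            )
        if len(set(self.fraction_ids)) != len(self.fraction_ids):
            raise SchemaError("fraction labels must be unique")
        if len(set(self.replicate_ids)) != len(self.replicate_ids):
            raise SchemaError("replicate labels must be unique")

    @property
    def n_fractions(self) -> int:
        return len(self.fraction_ids)

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_ids)

    def column_names(self) -> list[str]:
        """Expected abundance column names: ``<condition>_<rep>_<fraction>``."""
        return [
            f"{self.condition_id}_{rep}_{frac}"
            for rep in self.replicate_ids
            for frac in self.fraction_ids
        ]

    def compatible_with(self, other: "FractionScheme") -> bool:
        return (
            self.fraction_ids == other.fraction_ids
            and self.replicate_ids == other.replicate_ids
        )


@dataclass
class ProfileDataset:
    """Proteins x (replicate, fraction) abundance matrix for one condition.

    ``values`` is replicate-major: columns are ordered
    ``rep1 f1..fD, rep2 f1..fD, ...`` exactly as :meth:`FractionScheme.column_names`.
    """

    protein_ids: list[str]
    values: np.ndarray
    scheme: FractionScheme
    meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, p = self.values.shape
        if n != len(self.protein_ids):
            raise DimensionError(
                f"{len(self.protein_ids)} protein ids but {n} value rows"
            )
        expected = self.scheme.n_replicates * self.scheme.n_fractions
        if p != expected:
            raise DimensionError(
                f"values have {p} columns; scheme implies {expected}"
            )
        if len(set(self.protein_ids)) != n:
            raise DuplicateIdError("duplicate protein accessions in dataset")
        if self.meta is None:
            self.meta = pd.DataFrame(index=pd.Index(self.protein_ids, name="accession"))
        if "marker_class" not in self.meta.columns:
            self.meta = self.meta.assign(marker_class=UNKNOWN)

    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    def blocks(self) -> np.ndarray:
        """Values reshaped to (proteins, replicates, fractions)."""
        return self.values.reshape(
            self.n_proteins, self.scheme.n_replicates, self.scheme.n_fractions
        )

    def subset(self, keep: Sequence[str]) -> "ProfileDataset":
        """Row-subset the dataset to ``keep`` (order taken from ``keep``)."""
        index = {pid: i for i, pid in enumerate(self.protein_ids)}
        rows = [index[pid] for pid in keep]
        return ProfileDataset(
            protein_ids=list(keep),
            values=self.values[rows],
            scheme=self.scheme,
            meta=self.meta.loc[list(keep)].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values,
            index=pd.Index(self.protein_ids, name="accession"),
            columns=self.scheme.column_names(),
        )
        return pd.concat([self.meta, df], axis=1)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


@dataclass(frozen=True)
class MarkerMap:
    """Curated protein -> organelle class assignments."""

    entries: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", dict(self.entries))

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.entries.values())))

    def class_of(self, protein_id: str) -> str | None:
        return self.entries.get(protein_id)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.entries

    def members(self, cls: str) -> list[str]:
        return [p for p, c in self.entries.items() if c == cls]

    @classmethod
    def read_csv(cls, path: str | Path) -> "MarkerMap":
        df = pd.read_csv(path)
        if not {"accession", "organelle"}.issubset(df.columns):
            raise SchemaError("marker CSV requires columns: accession, organelle")
        if df["accession"].duplicated().any():
            raise DuplicateIdError("duplicate accession in marker map")
        return cls(dict(zip(df["accession"], df["organelle"])))

    def write_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"accession": list(self.entries), "organelle": list(self.entries.values())}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class ContaminantTable:
    """CRAPome-style contaminant frequencies in [0, 1] per accession."""

    frequencies: Mapping[str, float]

    def __post_init__(self) -> None:
        freqs = dict(self.frequencies)
        for pid, f in freqs.items():
            if not 0.0 <= f <= 1.0:
                raise SchemaError(f"contaminant frequency for {pid} outside [0,1]: {f}")
        object.__setattr__(self, "frequencies", freqs)

    def frequency(self, protein_id: str) -> float:
        return self.frequencies.get(protein_id, 0.0)

    @classmethod
    def read_csv(cls, path: str | Path) -> "ContaminantTable":
        df = pd.read_csv(path)
        if not {"accession", "freq"}.issubset(df.columns):
            raise SchemaError("contaminant CSV requires columns: accession, freq")
        return cls(dict(zip(df["accession"], df["freq"].astype(float))))


def default_blocklist() -> list[str]:
    """Accessions filtered regardless of frequency (keratins, albumin, trypsin)."""
    text = resources.files("vesicleshift.data").joinpath("blocklist.txt").read_text()
    return [
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]


def read_dataset(path: str | Path, scheme: FractionScheme) -> ProfileDataset:
    """Read a TSV/CSV quantitation table into a :class:`ProfileDataset`.

    The table must have an ``accession`` column, optional metadata columns
    (``gene``, ``marker_class``), and one abundance column per
    (replicate, fraction) named ``<condition>_<rep>_<fraction>``.  Rows with
    any missing abundance are dropped and the count logged.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    if "accession" not in df.columns:
        raise SchemaError("input table requires an 'accession' column")
    expected = scheme.column_names()
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(
            f"columns missing for scheme '{scheme.condition_id}': {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    if df["accession"].duplicated().any():
        dups = df.loc[df["accession"].duplicated(), "accession"].tolist()
        raise DuplicateIdError(f"duplicate accessions: {dups[:5]}")

    values = df[expected].apply(pd.to_numeric, errors="coerce")
    keep = values.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "read_dataset: dropped %d/%d proteins with missing values",
            n_dropped,
            len(df),
        )
    df = df.loc[keep]
    meta_cols = [c for c in df.columns if c not in expected and c != "accession"]
    meta = df[meta_cols].copy()
    meta.index = pd.Index(df["accession"], name="accession")
    return ProfileDataset(
        protein_ids=df["accession"].tolist(),
        values=values.loc[keep].to_numpy(dtype=float),
        scheme=scheme,
        meta=meta,
    )


def filter_contaminants(
    ds: ProfileDataset,
    tab: ContaminantTable,
    markers: MarkerMap,
    threshold: float = 0.1,
    blocklist: Iterable[str] | None = None,
) -> ProfileDataset:
    """Remove likely contaminants unless they are curated organelle markers.

    Proteins whose contaminant frequency is ``>= threshold`` are dropped, as
    are blocklisted accessions (keratins, serum albumin, trypsin by
    default), except that marker proteins are always retained.
    """
    if blocklist is None:
        blocklist = default_blocklist()
    block = set(blocklist)
    keep = [
        pid
        for pid in ds.protein_ids
        if pid in markers or (tab.frequency(pid) < threshold and pid not in block)
    ]
    n_removed = ds.n_proteins - len(keep)
    if n_removed:
        logger.info("filter_contaminants: removed %d proteins", n_removed)
    return ds.subset(keep)


def normalise_rows(ds: ProfileDataset) -> ProfileDataset:
    """Scale each (protein, replicate) fraction block to sum to one.

    Converts reporter-ion abundances to compositional profiles, the standard
    LOPIT convention; every downstream statistic operates on these.
    """
    blocks = ds.blocks().copy()
    sums = blocks.sum(axis=2)
    bad = np.nonzero(sums <= 0)
    if bad[0].size:
        offenders = sorted({ds.protein_ids[i] for i in bad[0]})
        raise DegenerateProfileError(
            f"all-zero replicate block(s) for proteins: {offenders[:10]}"
        )
    blocks /= sums[:, :, None]
    return replace(ds, values=blocks.reshape(ds.n_proteins, -1))


def _replace_zeros(block: np.ndarray) -> np.ndarray:
    """Replace zeros by half the smallest non-zero part, re-normalise."""
    block = np.asarray(block, dtype=float)
    if np.all(block > 0):
        return block
    nz = block[block > 0]
    if nz.size == 0:
        raise DegenerateProfileError("composition is all zeros")
    filled = np.where(block > 0, block, nz.min() / 2.0)
    return filled / filled.sum()


def alr_transform(profile: np.ndarray) -> np.ndarray:
    """Additive log-ratio transform of a D-part composition.

    Returns ``(log(x_1/x_D), ..., log(x_{D-1}/x_D))``; the last part is the
    reference.  Zeros are replaced by half the smallest non-zero part (then
    re-normalised) so the transform stays finite.  Applies row-wise to 2-D
    input.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.ndim == 1:
        if profile.size < 2:
            raise DimensionError("ALR requires at least 2 parts")
        x = _replace_zeros(profile)
        return np.log(x[:-1] / x[-1])
    if profile.shape[-1] < 2:
        raise DimensionError("ALR requires at least 2 parts")
    return np.stack([alr_transform(row) for row in profile])


def inverse_alr(z: np.ndarray) -> np.ndarray:
    """Map ALR coordinates back to the simplex (softmax with reference 0)."""
    z = np.asarray(z, dtype=float)
    if z.ndim == 1:
        e = np.exp(np.concatenate([z, [0.0]]))
        return e / e.sum()
    return np.stack([inverse_alr(row) for row in z])


def concatenate_replicates(ds: ProfileDataset) -> np.ndarray:
    """Per-protein feature vectors: replicate blocks concatenated in order.

    ``values`` is already stored replicate-major, so this is a copy that
    exists to make the ordering contract explicit at call sites.
    """
    return ds.values.copy()


def pca_projection(
    X: np.ndarray, n_components: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Mean-centred PCA scores with a deterministic sign convention.

    Each component's sign is fixed so its largest-magnitude loading is
    positive, making projections reproducible across runs and row orders.

    Returns ``(scores, explained_variance_ratio)``.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] < n_components:
        raise DimensionError(
            f"need >= {n_components} columns for {n_components} components"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    for j in range(n_components):
        loading = pca.components_[j]
        if loading[np.argmax(np.abs(loading))] < 0:
            scores[:, j] = -scores[:, j]
    return scores, pca.explained_variance_ratio_


def classify_supervised(
    ds: ProfileDataset,
    markers: MarkerMap,
    fdr: float = 0.05,
    n_folds: int = 5,
    random_state: int = 0,
) -> pd.Series:
    """Supervised organelle assignment with per-class FDR control.

    An RBF support-vector machine is trained on the concatenated marker
    profiles.  Per-class score thresholds are chosen on held-out markers
    (stratified cross-validation) so that the estimated false discovery
    proportion among assignments to each class is at most ``fdr``.
    Non-marker proteins below threshold are labelled ``"unassigned"``;
    marker proteins always keep their curated class.
    """
    X = concatenate_replicates(ds)
    pid_to_row = {pid: i for i, pid in enumerate(ds.protein_ids)}

    marker_ids = [p for p in ds.protein_ids if p in markers]
    labels = np.array([markers.class_of(p) for p in marker_ids])
    counts = pd.Series(labels).value_counts()
    small = counts[counts < 6].index.tolist()
    if small:
        warnings.warn(
            f"classes with < 6 markers excluded from classification: {small}",
            stacklevel=2,
        )
    usable = ~np.isin(labels, small)
    marker_ids = [p for p, u in zip(marker_ids, usable) if u]
    labels = labels[usable]
    Xm = X[[pid_to_row[p] for p in marker_ids]]
    classes = np.unique(labels)

    # Held-out decision scores on markers estimate per-class FDR thresholds.
    n_folds = min(n_folds, int(counts[~counts.index.isin(small)].min()))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=random_state)
    held_pred = np.empty(len(labels), dtype=object)
    held_score = np.empty(len(labels))
    for train, test in skf.split(Xm, labels):
        clf = SVC(kernel="rbf", C=10.0, gamma="scale", random_state=random_state)
        clf.fit(Xm[train], labels[train])
        dec = np.atleast_2d(clf.decision_function(Xm[test]))
        if dec.shape[1] == 1:  # binary: expand to two-column ovr-like scores
            dec = np.hstack([-dec, dec])
        best = np.argmax(dec, axis=1)
        held_pred[test] = clf.classes_[best]
        held_score[test] = dec[np.arange(len(test)), best]

    thresholds: dict[str, float] = {}
    for cls in classes:
        mask = held_pred == cls
        if not mask.any():
            thresholds[cls] = np.inf
            continue
        scores = held_score[mask]
        correct = labels[mask] == cls
        order = np.argsort(-scores)
        scores, correct = scores[order], correct[order]
        fdp = np.cumsum(~correct) / np.arange(1, len(scores) + 1)
        ok = np.nonzero(fdp <= fdr)[0]
        if ok.size == 0:
            thresholds[cls] = np.inf
        else:
            k = ok.max()
            # for fdr == 0 demand strictly above the best impostor score
            if fdr == 0.0 and (~correct[: k + 1]).any():
                thresholds[cls] = np.inf
            elif k == len(scores) - 1:
                # estimated FDP acceptable down to the lowest score: no cutoff
                thresholds[cls] = -np.inf
            else:
                thresholds[cls] = scores[k]

    final = SVC(kernel="rbf", C=10.0, gamma="scale", random_state=random_state)
    final.fit(Xm, labels)

    result = pd.Series(
        UNASSIGNED, index=pd.Index(ds.protein_ids, name="accession"), dtype=object
    )
    unknown_ids = [p for p in ds.protein_ids if p not in markers]
    if unknown_ids:
        Xu = X[[pid_to_row[p] for p in unknown_ids]]
        dec = np.atleast_2d(final.decision_function(Xu))
        if dec.shape[1] == 1:
            dec = np.hstack([-dec, dec])
        best = np.argmax(dec, axis=1)
        for pid, b, row in zip(unknown_ids, best, dec):
            cls = final.classes_[b]
            if row[b] >= thresholds[cls]:
                result[pid] = cls
    for pid in marker_ids:
        result[pid] = markers.class_of(pid)
    # markers of excluded small classes also keep their curated label
    for pid in ds.protein_ids:
        if pid in markers and result[pid] == UNASSIGNED:
            result[pid] = markers.class_of(pid)
    return result
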