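"""Synthetic LOPIT-DC data generator with known ground truth.

Emulates a two-condition differential-centrifugation experiment: ~10
fractions x 3 replicates, per-protein compositional profiles clustered by
organelle, a heavy-tailed outlier population, and a minority of proteins
whose treatment profile is partially displaced toward the mitochondrial
profile (partial relocalisation, displacement coefficient alpha).

Noise is logistic-normal: Gaussian perturbation in ALR space, then the
inverse transform back to the simplex.  Outliers are multivariate-T in ALR
space centred on the global template mean, mirroring the heavy-tailed
outlier component of the downstream mixture model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from vesicleshift.errors import ConfigError, SeparationError
from vesicleshift.profiles import (
    FractionScheme,
    MarkerMap,
    ProfileDataset,
    alr_transform,
    inverse_alr,
)

DEFAULT_CLASSES = (
    "mitochondria",
    "nucleus",
    "er",
    "golgi",
    "lysosome",
    "plasma_membrane",
    "endosome",
    "cytosol",
)


@dataclass(frozen=True)
class OrganelleTemplate:
    """Mean fractionation profile of one organelle class."""

    label: str
    mean: np.ndarray  # simplex vector over D fractions
    spread: float = 1.0  # multiplier on the replicate noise scale

    def __post_init__(self) -> None:
        m = np.asarray(self.mean, dtype=float)
        if not np.isclose(m.sum(), 1.0):
            raise ConfigError(f"template '{self.label}' mean must sum to 1")
        if self.spread <= 0:
            raise ConfigError("template spread must be positive")
        object.__setattr__(self, "mean", m)


@dataclass
class SimulationConfig:
    """Study-design parameters for one simulated comparison.

    Defaults emulate the scale of a golgin-relocation LOPIT-DC comparison:
    10 fractions, 3 replicates, a few percent outliers, and a small minority
    of proteins partially displaced toward the mitochondrial profile in the
    treatment condition (alpha in [0.5, 1] = half-way to fully mitochondrial).
    """

    n_proteins: int = 2000
    n_markers_per_class: int = 25
    n_fractions: int = 10
    n_replicates: int = 3
    conditions: tuple[str, str] = ("control", "treatment")
    classes: tuple[str, ...] = DEFAULT_CLASSES
    outlier_fraction: float = 0.05
    reloc_fraction: float = 0.025
    reloc_alpha_range: tuple[float, float] = (0.5, 1.0)
    noise_sd: float = 0.25  # replicate noise, ALR scale
    separation_floor: float = 3.0  # min pairwise Aitchison distance
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.outlier_fraction <= 1.0:
            raise ConfigError("outlier_fraction must be in [0,1]")
        if not 0.0 <= self.reloc_fraction <= 1.0:
            raise ConfigError("reloc_fraction must be in [0,1]")
        if self.outlier_fraction + self.reloc_fraction > 1.0:
            raise ConfigError("outlier_fraction + reloc_fraction exceeds 1")
        lo, hi = self.reloc_alpha_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigError("reloc_alpha_range must be within [0,1]")
        if "mitochondria" not in self.classes:
            raise ConfigError("classes must include 'mitochondria'")


@dataclass
class SimulatedTruth:
    """Ground-truth labels for every simulated protein."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: accession, organelle, is_marker, is_outlier, is_relocated, alpha

    def relocated_ids(self) -> list[str]:
        return self.table.loc[self.table["is_relocated"], "accession"].tolist()

    def outlier_ids(self) -> list[str]:
        return self.table.loc[self.table["is_outlier"], "accession"].tolist()

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _aitchison_dist(a: np.ndarray, b: np.ndarray) -> float:
    """Aitchison distance = Euclidean distance between CLR vectors."""
    ca = np.log(a) - np.log(a).mean()
    cb = np.log(b) - np.log(b).mean()
    return float(np.linalg.norm(ca - cb))


def make_templates(
    classes: tuple[str, ...] = DEFAULT_CLASSES,
    n_fractions: int = 10,
    seed: int = 0,
    separation_floor: float = 3.0,
    max_tries: int = 200,
) -> list[OrganelleTemplate]:
    """Draw organelle template profiles separated in Aitchison geometry.

    Each class profile is a smooth bump over the fraction axis (organelles
    enrich in a few adjacent centrifugation fractions) plus a seeded ALR
    jitter; draws are retried until every pairwise Aitchison distance
    reaches ``separation_floor``.  Deterministic given ``seed``.
    """
    if len(classes) < 2:
        raise ConfigError("need at least 2 classes")
    if "mitochondria" not in classes:
        raise ConfigError("classes must include 'mitochondria'")
    rng = np.random.default_rng(seed)
    K, D = len(classes), n_fractions
    centers = np.linspace(0, D - 1, K)
    grid = np.arange(D)

    for _ in range(max_tries):
        means = []
        for k in range(K):
            bump = np.exp(-((grid - centers[k]) ** 2) / (2 * 1.2**2)) + 0.03
            base = bump / bump.sum()
            z = alr_transform(base) + rng.normal(0.0, 0.9, size=D - 1)
            means.append(inverse_alr(z))
        ok = all(
            _aitchison_dist(means[i], means[j]) >= separation_floor
            for i in range(K)
            for j in range(i + 1, K)
        )
        if ok:
            return [
                OrganelleTemplate(label=c, mean=m) for c, m in zip(classes, means)
            ]
    raise SeparationError(
        f"could not separate {K} templates to floor {separation_floor} "
        f"in {max_tries} tries"
    )


def simulate_dataset(
    cfg: SimulationConfig,
    templates: list[OrganelleTemplate] | None = None,
) -> tuple[dict[str, ProfileDataset], MarkerMap, SimulatedTruth]:
    """Simulate per-condition datasets with known organelle ground truth.

    Each protein's per-replicate profile is a logistic-normal perturbation
    of its class template.  Outliers are drawn from a multivariate-T spread
    in ALR space.  In the treatment condition, relocated proteins' template
    ALR vectors are replaced by ``(1 - alpha) * source + alpha * mito``
    before perturbation.  Markers are never outliers nor relocated.

    Returns ``(datasets_by_condition, marker_map, truth)``.
    """
    rng = np.random.default_rng(cfg.seed)
    if templates is None:
        templates = make_templates(
            cfg.classes, cfg.n_fractions, seed=cfg.seed,
            separation_floor=cfg.separation_floor,
        )
    by_label = {t.label: t for t in templates}
    if "mitochondria" not in by_label:
        raise ConfigError("templates must include a 'mitochondria' class")
    labels = [t.label for t in templates]
    K, D, R = len(labels), cfg.n_fractions, cfg.n_replicates
    template_alr = {lab: alr_transform(by_label[lab].mean) for lab in labels}
    mito_alr = template_alr["mitochondria"]

    n_markers = cfg.n_markers_per_class * K
    if n_markers >= cfg.n_proteins:
        raise ConfigError("n_proteins must exceed total marker count")
    n = cfg.n_proteins

    # class assignment: markers first (round-robin), unknowns uniform
    organelle = np.empty(n, dtype=object)
    is_marker = np.zeros(n, dtype=bool)
    for k, lab in enumerate(labels):
        lo = k * cfg.n_markers_per_class
        organelle[lo : lo + cfg.n_markers_per_class] = lab
        is_marker[lo : lo + cfg.n_markers_per_class] = True
    organelle[n_markers:] = rng.choice(labels, size=n - n_markers)

    # outlier / relocated status among non-markers only; relocation sources
    # exclude mitochondria- and nucleus-like compartments (vesicle cargo
    # originates from the secretory/endosomal system, and residents of the
    # pre-filtered compartments cannot meaningfully move toward them)
    unknown_idx = np.nonzero(~is_marker)[0]
    n_out = int(round(cfg.outlier_fraction * n))
    n_rel = int(round(cfg.reloc_fraction * n))
    if n_out + n_rel > unknown_idx.size:
        raise ConfigError("too few non-marker proteins for outlier+reloc fractions")
    is_outlier = np.zeros(n, dtype=bool)
    is_relocated = np.zeros(n, dtype=bool)
    out_idx = rng.choice(unknown_idx, size=n_out, replace=False)
    is_outlier[out_idx] = True
    fixed = {
        lab
        for lab in labels
        if any(pat in lab.lower() for pat in ("mito", "nucle", "chromatin"))
    }
    rel_pool = np.array(
        [i for i in unknown_idx if not is_outlier[i] and organelle[i] not in fixed]
    )
    if n_rel > rel_pool.size:
        raise ConfigError("too few mobile-compartment proteins for reloc_fraction")
    is_relocated[rng.choice(rel_pool, size=n_rel, replace=False)] = True
    alpha = np.zeros(n)
    lo, hi = cfg.reloc_alpha_range
    alpha[is_relocated] = rng.uniform(lo, hi, size=n_rel)

    accessions = [f"SIM{i:05d}" for i in range(n)]
    # global outlier spread: T distribution over the template cloud
    centre = np.mean([template_alr[lab] for lab in labels], axis=0)
    cloud_sd = np.std([template_alr[lab] for lab in labels], axis=0).mean()
    outlier_scale = max(cloud_sd, 1.0)
    outlier_df = 4.0
    # outlier profiles are common to both conditions (mislocalisation, not
    # relocation): draw their base ALR position once
    outlier_base = {
        int(i): centre
        + rng.standard_t(outlier_df, size=D - 1) * outlier_scale
        for i in np.nonzero(is_outlier)[0]
    }

    datasets: dict[str, ProfileDataset] = {}
    for cond in cfg.conditions:
        treat = cond != cfg.conditions[0]
        values = np.empty((n, R * D))
        for i in range(n):
            if is_outlier[i]:
                base = outlier_base[int(i)]
            else:
                base = template_alr[organelle[i]]
                if treat and is_relocated[i]:
                    base = (1.0 - alpha[i]) * base + alpha[i] * mito_alr
            noise = rng.normal(0.0, cfg.noise_sd, size=(R, D - 1))
            comps = inverse_alr(base[None, :] + noise)
            # emulate raw reporter intensities: scale by a lognormal total
            totals = rng.lognormal(mean=np.log(1e6), sigma=0.25, size=R)
            values[i] = (comps * totals[:, None]).ravel()
        scheme = FractionScheme(
            fraction_ids=tuple(f"F{j + 1}" for j in range(D)),
            replicate_ids=tuple(f"R{r + 1}" for r in range(R)),
            condition_id=cond,
        )
        meta = pd.DataFrame(
            {
                "gene": [f"GENE{i}" for i in range(n)],
                "marker_class": np.where(is_marker, organelle, "unknown"),
            },
            index=pd.Index(accessions, name="accession"),
        )
        datasets[cond] = ProfileDataset(
            protein_ids=list(accessions), values=values, scheme=scheme, meta=meta
        )

    markers = MarkerMap(
        {acc: organelle[i] for i, acc in enumerate(accessions) if is_marker[i]}
    )
    truth = SimulatedTruth(
        pd.DataFrame(
            {
                "accession": accessions,
                "organelle": organelle,
                "is_marker": is_marker,
                "is_outlier": is_outlier,
                "is_relocated": is_relocated,
                "alpha": alpha,
            }
        )
    )
    return datasets, markers, truth
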