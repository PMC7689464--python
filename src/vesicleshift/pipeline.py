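"""End-to-end differential localisation comparison.

Stages, in order: contaminant filter -> per-replicate sum normalisation ->
TAGM-MAP fit and mitochondria/nucleus pre-filter on the CONTROL condition
-> per-protein GP Bayes factor (control vs treatment, ALR profiles) ->
per-condition robust mitochondrial covariances -> per-protein log2
MitoRatio -> dual-threshold hit calling.  Defaults for the thresholds are
the calibrated values log2(MitoRatio) >= 0.40 and log_e(Bayes factor)
>= 14.0.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from vesicleshift.errors import VesicleShiftError
from vesicleshift.gp_two_sample import GPHyperpriors, log_bayes_factor
from vesicleshift.mito_ratio import mito_ratio_table
from vesicleshift.profiles import (
    ContaminantTable,
    FractionScheme,
    MarkerMap,
    ProfileDataset,
    alr_transform,
    filter_contaminants,
    normalise_rows,
    read_dataset,
)
from vesicleshift.tagm import (
    default_priors,
    fit_tagm_map,
    match_discard_classes,
    posterior_localisation,
    prefilter_discard,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All options for one control-versus-treatment comparison.

    Datasets and annotation tables may be given as in-memory objects or as
    file paths (paths require ``control_scheme``/``treatment_scheme``).
    """

    control: ProfileDataset | str | Path = None  # type: ignore[assignment]
    treatment: ProfileDataset | str | Path = None  # type: ignore[assignment]
    markers: MarkerMap | str | Path = None  # type: ignore[assignment]
    contaminants: ContaminantTable | str | Path | None = None
    control_scheme: FractionScheme | None = None
    treatment_scheme: FractionScheme | None = None
    bait: tuple[str, ...] = ()
    bf_threshold: float = 14.0  # log-e scale
    ratio_threshold: float = 0.40  # log2 scale
    contaminant_threshold: float = 0.1
    discard_classes: tuple[str, ...] | None = None  # None -> pattern match
    mito_class: str = "mitochondria"
    gp_priors: GPHyperpriors = field(default_factory=GPHyperpriors)
    tagm_max_iter: int = 200
    tagm_tol: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.bf_threshold) or not np.isfinite(
            self.ratio_threshold
        ):
            raise VesicleShiftError("thresholds must be finite")


@dataclass
class HitTable:
    """Primary pipeline output: per-protein statistics and hit flags."""

    table: pd.DataFrame
    # columns: gene, tagm_class, logbf, log2_mitoratio, is_bait, is_hit
    counts: dict[str, int]
    config: PipelineConfig

    @property
    def hits(self) -> list[str]:
        """Hit accessions, excluding bait proteins."""
        t = self.table
        return t.index[t["is_hit"] & ~t["is_bait"]].tolist()

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t")


def _load_dataset(obj, scheme) -> ProfileDataset:
    if isinstance(obj, ProfileDataset):
        return obj
    if scheme is None:
        raise VesicleShiftError("a FractionScheme is required to read a dataset path")
    return read_dataset(obj, scheme)


def _load_markers(obj) -> MarkerMap:
    return obj if isinstance(obj, MarkerMap) else MarkerMap.read_csv(obj)


def _load_contaminants(obj) -> ContaminantTable:
    if obj is None:
        return ContaminantTable({})
    return obj if isinstance(obj, ContaminantTable) else ContaminantTable.read_csv(obj)


def _alr_blocks(ds: ProfileDataset) -> np.ndarray:
    """(proteins, replicates, D-1) per-replicate ALR profiles."""
    blocks = ds.blocks()
    n, r, d = blocks.shape
    out = np.empty((n, r, d - 1))
    for i in range(n):
        out[i] = alr_transform(blocks[i])
    return out


def run_comparison(cfg: PipelineConfig) -> HitTable:
    """Execute the full comparison and return the hit table.

    Hits are proteins with log-e Bayes factor >= ``bf_threshold`` AND log2
    MitoRatio >= ``ratio_threshold``; bait accessions are flagged and
    reported separately from the hit count.
    """
    try:
        control = _load_dataset(cfg.control, cfg.control_scheme)
        treatment = _load_dataset(cfg.treatment, cfg.treatment_scheme)
        markers = _load_markers(cfg.markers)
        contaminants = _load_contaminants(cfg.contaminants)
    except VesicleShiftError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate stage
        raise VesicleShiftError(f"input loading failed: {exc}") from exc

    if not control.scheme.compatible_with(treatment.scheme):
        raise VesicleShiftError(
            "control and treatment fraction schemes are incompatible"
        )

    counts: dict[str, int] = {
        "control_input": control.n_proteins,
        "treatment_input": treatment.n_proteins,
    }

    # stage: contaminant filter
    control = filter_contaminants(
        control, contaminants, markers, threshold=cfg.contaminant_threshold
    )
    treatment = filter_contaminants(
        treatment, contaminants, markers, threshold=cfg.contaminant_threshold
    )

    # stage: shared protein universe
    shared = [p for p in control.protein_ids if p in set(treatment.protein_ids)]
    counts["analysed"] = len(shared)
    logger.info("analysed proteins (post-filter intersection): %d", len(shared))
    if not shared:
        raise VesicleShiftError("empty protein universe after filtering")
    control = control.subset(shared)
    treatment = treatment.subset(shared)

    # stage: normalise
    control = normalise_rows(control)
    treatment = normalise_rows(treatment)

    # per-replicate ALR profiles: TAGM features and GP test inputs
    alr_control = _alr_blocks(control)
    alr_treatment = _alr_blocks(treatment)

    # stage: TAGM pre-filter on the control condition.  Fitted in ALR
    # coordinates: sum-constrained compositions have a rank-deficient
    # covariance, which the log-ratio representation removes.
    Xc = alr_control.reshape(len(shared), -1)
    marker_labels = np.array(
        [markers.class_of(p) if p in markers else None for p in shared],
        dtype=object,
    )
    priors = default_priors(Xc, len(markers.classes))
    fit = fit_tagm_map(
        Xc,
        marker_labels,
        priors,
        max_iter=cfg.tagm_max_iter,
        tol=cfg.tagm_tol,
        class_labels=tuple(markers.classes),
    )
    post = posterior_localisation(fit, Xc, protein_ids=shared)
    discard = (
        set(cfg.discard_classes)
        if cfg.discard_classes is not None
        else match_discard_classes(fit.class_labels)
    )
    retained = prefilter_discard(post, discard, markers=markers)
    counts["retained_after_prefilter"] = len(retained)
    logger.info("retained after mito/nucleus pre-filter: %d", len(retained))
    if not retained:
        raise VesicleShiftError("pre-filter removed every protein")
    tagm_class = pd.Series(post.map_class, index=pd.Index(shared, name="accession"))

    # stage: per-protein GP Bayes factor on ALR profiles
    row_of = {p: i for i, p in enumerate(shared)}
    logbf = np.empty(len(retained))
    for i, pid in enumerate(retained):
        j = row_of[pid]
        logbf[i] = log_bayes_factor(
            alr_control[j], alr_treatment[j], cfg.gp_priors
        ).log_bf

    # stage: MitoRatio with per-condition robust mito covariances
    mrr = mito_ratio_table(
        control,
        treatment,
        markers,
        mito_class=cfg.mito_class,
        protein_ids=retained,
        random_state=cfg.seed,
    )

    gene = (
        control.meta["gene"]
        if "gene" in control.meta.columns
        else pd.Series("", index=control.meta.index)
    )
    table = pd.DataFrame(
        {
            "gene": gene.reindex(retained),
            "tagm_class": tagm_class.reindex(retained),
            "logbf": logbf,
            "log2_mitoratio": mrr.table["log2_mitoratio"].reindex(retained),
            "d2_control": mrr.table["d2_control"].reindex(retained),
            "d2_treatment": mrr.table["d2_treatment"].reindex(retained),
        },
        index=pd.Index(retained, name="accession"),
    )
    table["is_bait"] = table.index.isin(cfg.bait)
    table["is_hit"] = (table["logbf"] >= cfg.bf_threshold) & (
        table["log2_mitoratio"] >= cfg.ratio_threshold
    )
    counts["hits"] = int((table["is_hit"] & ~table["is_bait"]).sum())
    counts["bait_within_threshold"] = int(
        (table["is_hit"] & table["is_bait"]).sum()
    )
    return HitTable(table=table, counts=counts, config=cfg)


@dataclass
class CalibrationResult:
    bf_threshold: float
    ratio_threshold: float
    feasible: bool


def calibrate_thresholds(
    scores: pd.DataFrame,
    positives: set[str],
    negatives: set[str],
) -> CalibrationResult:
    """Choose dual thresholds from known positives and negatives.

    ``scores`` must have columns ``logbf`` and ``log2_mitoratio`` indexed by
    accession.  Returns the largest (bf, ratio) pair on the observed score
    grid such that every positive passes both thresholds and no negative
    passes both.  If no such pair exists, returns the pair maximising
    (positives covered - negatives covered), ties broken toward stricter
    thresholds, with ``feasible=False``.
    """
    if not positives:
        raise VesicleShiftError("positives must be non-empty")
    if positives & negatives:
        raise VesicleShiftError("positives and negatives overlap")
    missing = (positives | negatives) - set(scores.index)
    if missing:
        raise VesicleShiftError(f"accessions absent from scores: {sorted(missing)[:5]}")

    pos = scores.loc[sorted(positives)]
    neg = scores.loc[sorted(negatives)] if negatives else scores.iloc[0:0]
    bf_star = float(pos["logbf"].min())
    ratio_star = float(pos["log2_mitoratio"].min())
    if neg.empty or not (
        (neg["logbf"] >= bf_star) & (neg["log2_mitoratio"] >= ratio_star)
    ).any():
        return CalibrationResult(bf_star, ratio_star, feasible=True)

    # infeasible: any pair covering all positives also admits a negative
    cand_bf = np.unique(scores["logbf"].to_numpy())
    cand_ratio = np.unique(scores["log2_mitoratio"].to_numpy())
    best = None
    for bf in cand_bf:
        for r in cand_ratio:
            npos = int(
                ((pos["logbf"] >= bf) & (pos["log2_mitoratio"] >= r)).sum()
            )
            nneg = int(
                ((neg["logbf"] >= bf) & (neg["log2_mitoratio"] >= r)).sum()
            )
            key = (npos - nneg, bf, r)
            if best is None or key > best[0]:
                best = (key, bf, r)
    _, bf, r = best
    return CalibrationResult(float(bf), float(r), feasible=False)


def hit_plot(
    hit_table: HitTable,
    path: str | Path,
    truncate_axes: bool = False,
) -> Path:
    """Scatter of log2 MitoRatio vs log-e Bayes factor with threshold lines.

    Hits are highlighted and bait proteins annotated; with
    ``truncate_axes`` the axes start at the threshold cut-offs.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = hit_table.table
    cfg = hit_table.config
    fig, ax = plt.subplots(figsize=(6, 5))
    bg = t[~t["is_hit"]]
    hits = t[t["is_hit"] & ~t["is_bait"]]
    ax.scatter(bg["logbf"], bg["log2_mitoratio"], s=8, c="0.7", label="other")
    if len(hits):
        ax.scatter(
            hits["logbf"], hits["log2_mitoratio"], s=14, c="crimson", label="hit"
        )
    ax.axvline(cfg.bf_threshold, ls="--", lw=0.8, c="k")
    ax.axhline(cfg.ratio_threshold, ls="--", lw=0.8, c="k")
    for acc in t.index[t["is_bait"]]:
        row = t.loc[acc]
        ax.annotate(
            str(row.get("gene", acc)) or acc,
            (row["logbf"], row["log2_mitoratio"]),
            fontsize=8,
            fontweight="bold",
        )
        ax.scatter([row["logbf"]], [row["log2_mitoratio"]], s=20, c="navy")
    if truncate_axes:
        ax.set_xlim(left=cfg.bf_threshold)
        ax.set_ylim(bottom=cfg.ratio_threshold)
    ax.set_xlabel("log$_e$(Bayes factor)")
    ax.set_ylabel("log$_2$(MitoRatio)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def write_manifest(hit_table: HitTable, path: str | Path) -> None:
    """Per-stage counts and thresholds as a JSON run manifest."""
    cfg = hit_table.config
    manifest = {
        "counts": hit_table.counts,
        "bf_threshold": cfg.bf_threshold,
        "ratio_threshold": cfg.ratio_threshold,
        "contaminant_threshold": cfg.contaminant_threshold,
        "seed": cfg.seed,
        "bait": list(cfg.bait),
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
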