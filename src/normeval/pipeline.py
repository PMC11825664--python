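"""Run configuration, validation, and the end-to-end evaluation driver.

``run_all`` wires a dataset bundle through every requested metric --
RQI on unseen-healthy pairs, AHI from the four embedded sets, CACI on
pathological pairs with masks, the fused score, box-based detection F1,
and ceiling Dice per lesion-size stratum -- and returns a report that
echoes every parameter and backend used, so any number in it can be
recomputed from the echo alone.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import yaml

from . import detection_eval as de
from . import distribution_metrics as dm
from . import restoration_metrics as rm
from .errors import UsageError
from .feature_backends import get_embedding_backend, get_perceptual_backend
from .image_io import (
    AnnotationSet,
    DatasetBundle,
    ImageSample,
    MetricReport,
    load_annotations,
    load_images_dir,
)

logger = logging.getLogger("normeval")

ALL_METRICS = ("rqi", "ahi", "caci", "fused", "detect", "dice")


@dataclass
class RunConfig:
    """Everything one evaluation run depends on.

    Paths may be None when the corresponding metric is not selected or the
    bundle is passed in memory. CLI flags override file values; the merged
    effective config is embedded verbatim in the report.
    """

    # data paths
    healthy_dir: str | None = None
    unseen_dir: str | None = None
    restored_unseen_dir: str | None = None
    pathological_dir: str | None = None
    restored_dir: str | None = None
    mask_dir: str | None = None
    box_file: str | None = None
    brain_mask_dir: str | None = None

    # backends
    perceptual_backend: str = "toy"
    embedding_backend: str = "toy"

    # metric parameters
    rqi_min_lp: float = 0.0
    rqi_max_lp: float = 25.0
    rqi_cap_at_max: bool = True
    ahi_eps: float = dm.DEFAULT_EPS
    caci_eps: float = rm.DEFAULT_EPS
    binarize_strategy: str = "healthy_quantile"
    binarize_threshold: float | None = None
    binarize_quantile: float = 0.95
    min_overlap: float = de.MIN_OVERLAP_DEFAULT
    dice_thresholds: int | Literal["exhaustive"] = 100
    strata_mode: Literal["quantile", "fixed"] = "quantile"
    strata_cuts: tuple[float, float] | None = None
    min_fid_set_size: int = dm.SMALL_SAMPLE_WARNING_N

    metrics: tuple[str, ...] = ALL_METRICS
    seed: int = 0
    out_path: str | None = None
    out_format: str = "json"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise UsageError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**raw)
        if isinstance(cfg.metrics, list):
            cfg.metrics = tuple(cfg.metrics)
        if isinstance(cfg.strata_cuts, list):
            cfg.strata_cuts = tuple(cfg.strata_cuts)  # type: ignore[assignment]
        return cfg

    def echo(self) -> dict:
        d = asdict(self)
        d["metrics"] = list(self.metrics)
        return d


@dataclass
class Finding:
    """One machine-readable validation finding."""

    severity: Literal["error", "warning"]
    message: str


def validate_config(
    config: RunConfig, bundle: DatasetBundle | None = None
) -> list[Finding]:
    """Check a config (and optionally a bundle) without throwing."""
    findings: list[Finding] = []

    def err(msg: str) -> None:
        findings.append(Finding("error", msg))

    def warn(msg: str) -> None:
        findings.append(Finding("warning", msg))

    if config.rqi_max_lp <= config.rqi_min_lp:
        err(f"rqi_max_lp ({config.rqi_max_lp}) must exceed rqi_min_lp "
            f"({config.rqi_min_lp})")
    for name in ("ahi_eps", "caci_eps"):
        if getattr(config, name) <= 0:
            err(f"{name} must be positive")
    if not 0 < config.min_overlap <= 1:
        err(f"min_overlap must be in (0, 1], got {config.min_overlap}")
    if config.binarize_strategy == "fixed" and (
        config.binarize_threshold is None or config.binarize_threshold < 0
    ):
        err("fixed binarization needs binarize_threshold >= 0")
    if config.binarize_strategy == "healthy_quantile" and not (
        0 < config.binarize_quantile < 1
    ):
        err(f"binarize_quantile must be in (0, 1), got {config.binarize_quantile}")
    if config.strata_mode == "fixed":
        if config.strata_cuts is None or config.strata_cuts[0] >= config.strata_cuts[1]:
            err(f"fixed strata need cuts lo < hi, got {config.strata_cuts}")
    unknown = set(config.metrics) - set(ALL_METRICS)
    if unknown:
        err(f"unknown metrics selected: {sorted(unknown)}")

    if bundle is not None:
        for name, n in (
            ("healthy_ref", len(bundle.healthy_ref)),
            ("unseen_healthy", len(bundle.unseen_healthy)),
            ("pathological", len(bundle.pathological)),
        ):
            if "ahi" in config.metrics and 0 < n < config.min_fid_set_size:
                warn(
                    f"set {name!r} has only {n} images; Frechet-distance "
                    f"estimates below n={config.min_fid_set_size} are biased"
                )
    return findings


def load_bundle(config: RunConfig) -> tuple[DatasetBundle, AnnotationSet | None]:
    """Assemble a bundle from the directories named in the config."""
    def maybe(directory: str | None) -> list[ImageSample]:
        return load_images_dir(directory) if directory else []

    healthy = maybe(config.healthy_dir)
    unseen_inputs = maybe(config.unseen_dir)
    restored_unseen = {s.id: s for s in maybe(config.restored_unseen_dir)}
    pathological = maybe(config.pathological_dir)
    restored = maybe(config.restored_dir)

    annotations = None
    if config.mask_dir or config.box_file:
        shapes = {s.id: s.shape for s in pathological}
        annotations = load_annotations(
            mask_dir=config.mask_dir,
            box_file=config.box_file,
            brain_mask_dir=config.brain_mask_dir,
            image_shapes=shapes,
        )
    bundle = DatasetBundle(
        healthy_ref=healthy,
        unseen_healthy=[(s, restored_unseen.get(s.id)) for s in unseen_inputs],
        pathological=pathological,
        restored_pathological=restored,
        annotations=annotations,
    )
    bundle.validate()
    return bundle, annotations


def _unseen_pairs(bundle: DatasetBundle) -> list[tuple[ImageSample, ImageSample]]:
    pairs = [(inp, r) for inp, r in bundle.unseen_healthy if r is not None]
    if not pairs:
        raise UsageError(
            "metric 'rqi' needs unseen-healthy restorations, but none are present"
        )
    return pairs


def run_all(
    config: RunConfig,
    bundle: DatasetBundle | None = None,
    annotations: AnnotationSet | None = None,
) -> MetricReport:
    """Compute every selected metric on a bundle (loaded from the config's
    paths when not supplied) and return the full report."""
    findings = validate_config(config, bundle)
    errors = [f.message for f in findings if f.severity == "error"]
    if errors:
        raise UsageError("invalid config: " + "; ".join(errors))
    for f in findings:
        logger.warning("%s", f.message)

    if bundle is None:
        bundle, annotations = load_bundle(config)
    if annotations is None:
        annotations = bundle.annotations

    selected = set(config.metrics)
    if "fused" in selected:
        selected |= {"rqi", "ahi", "caci"}
    report = MetricReport(config_echo=config.echo())

    if "rqi" in selected:
        backend = get_perceptual_backend(config.perceptual_backend)
        backend.scale_max = config.rqi_max_lp
        rqi_cfg = rm.RQIConfig(
            min_lp=config.rqi_min_lp,
            max_lp=config.rqi_max_lp,
            cap_at_max=config.rqi_cap_at_max,
        )
        report.rqi = rm.rqi(_unseen_pairs(bundle), backend, rqi_cfg)
        logger.info("RQI = %.4f over %d unseen-healthy pairs",
                    report.rqi, len(bundle.unseen_healthy))

    if "ahi" in selected:
        embedder = get_embedding_backend(config.embedding_backend)
        if not bundle.restored_pathological:
            raise UsageError(
                "metric 'ahi' needs the restored_pathological set, "
                "but it is empty"
            )
        ahi_value, components = dm.ahi_from_bundle(
            bundle, embedder, eps=config.ahi_eps
        )
        report.ahi = ahi_value
        report.fid_components = {
            "fid_rp_h": components.fid_rp_h,
            "fid_uh_h": components.fid_uh_h,
            "fid_p_h": components.fid_p_h,
        }
        logger.info("AHI = %.4f (FID_RP,H=%.4g, FID_UH,H=%.4g, FID_P,H=%.4g)",
                    ahi_value, components.fid_rp_h, components.fid_uh_h,
                    components.fid_p_h)

    needs_masks = selected & {"caci", "dice"}
    if needs_masks and (annotations is None or not annotations.masks):
        raise UsageError(
            f"metrics {sorted(needs_masks)} need anomaly masks, "
            "but none are present"
        )

    if "caci" in selected:
        assert annotations is not None
        value, _, excluded = rm.caci_detail(
            bundle.pathological_pairs(), annotations.masks, eps=config.caci_eps
        )
        report.caci = value
        report.caci_excluded_empty_masks = excluded
        if excluded:
            logger.info("CACI excluded %d empty-mask pairs", excluded)
        logger.info("CACI = %.4f", value)

    if "fused" in config.metrics:
        assert report.rqi is not None and report.ahi is not None
        assert report.caci is not None
        report.fused = rm.fused_metric(report.rqi, report.ahi, report.caci)
        logger.info("fused = %.4f", report.fused)

    maps: list[de.AnomalyMap] | None = None
    if selected & {"detect", "dice"}:
        maps = [
            de.anomaly_map(x, xr) for x, xr in bundle.pathological_pairs()
        ]

    if "detect" in selected:
        assert maps is not None
        if annotations is None or not annotations.boxes:
            raise UsageError("metric 'detect' needs boxes, but none are present")
        reference = None
        if config.binarize_strategy == "healthy_quantile":
            reference = [
                de.anomaly_map(inp, r) for inp, r in bundle.unseen_healthy
                if r is not None
            ]
            if not reference:
                raise UsageError(
                    "healthy_quantile binarization needs unseen-healthy "
                    "restorations for the reference maps"
                )
        threshold = de.resolve_threshold(
            config.binarize_strategy,
            threshold=config.binarize_threshold,
            quantile=config.binarize_quantile,
            reference_maps=reference,
        )
        logger.info("binarization threshold = %.6g (%s)",
                    threshold, config.binarize_strategy)
        cases = []
        for m in maps:
            if m.id not in annotations.boxes:
                continue
            binary = (m.scores > threshold).astype("uint8")
            cases.append(
                de.evaluate_case(
                    binary,
                    annotations.boxes[m.id],
                    brain_mask=annotations.brain_masks.get(m.id),
                    min_overlap=config.min_overlap,
                    case_id=m.id,
                )
            )
        per_class, overall = de.dataset_f1(cases)
        report.per_class_detection = per_class
        report.overall_detection = {**overall, "threshold": threshold}
        logger.info("detection: %d/%d boxes, F1 = %.4f",
                    overall["n_detected"], overall["n_total"], overall["f1"])

    if "dice" in selected:
        assert maps is not None and annotations is not None
        masked = {k: v for k, v in annotations.masks.items()}
        strata = de.stratify_lesions(
            masked, mode=config.strata_mode, cuts=config.strata_cuts
        )
        results = de.ceiling_dice(
            [m for m in maps if m.id in masked],
            masked,
            n_thresholds=config.dice_thresholds,
            strata=strata,
        )
        report.ceiling_dice = {
            r.stratum: {
                "dice": r.dice,
                "threshold": r.threshold,
                "n_cases": r.n_cases,
                "dice_mean_case": r.dice_mean_case,
                "degenerate": r.degenerate,
            }
            for r in results
        }
        for r in results:
            logger.info("ceiling Dice [%s]: %.4f at t=%.4g over %d cases%s",
                        r.stratum, r.dice, r.threshold, r.n_cases,
                        " (degenerate)" if r.degenerate else "")

    return report
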