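"""Self-contained validation experiments on synthetic ground truth.

Each function runs the pipeline end-to-end on simulated inputs and
measures agreement with an independent oracle or with the simulator's
exact ground truth.  They back both the acceptance test suite and the
standalone acceptance report script.
"""

from __future__ import annotations

import numpy as np

from epimux import scenes
from epimux.algebra import epitope_report, overlap_area, total_area, unique_area
from epimux.image_io import AnalysisConfig
from epimux.morphometry import label_aggregates, morphology_distribution
from epimux.pk import fit_retention, measure_timepoint, normalize_series
from epimux.segment import otsu_threshold, segment_channel
from epimux.stats import one_way_anova, pearson, rm_one_way_anova

__all__ = [
    "mask_algebra_conservation",
    "otsu_oracle_agreement",
    "ground_truth_recovery",
    "morphology_recovery",
    "pk_recovery",
    "pk_time_effect_rates",
    "anova_type_i_rate",
    "cohort_correlation",
    "EXPECTED_CLASS",
]

EXPECTED_CLASS = {
    "lewy_body": "lewy_body",
    "lewy_neurite": "lewy_neurite",
    "punctate_lysosomal": "punctate",
    "glial": "lewy_neurite",
}


# ---------------------------------------------------------------------------
# 1. mask-algebra conservation


def mask_algebra_conservation(n_triples: int = 1000, shape=(64, 64), seed: int = 0) -> dict:
    """Additivity and per-pixel oracle agreement over random mask triples."""
    rng = np.random.default_rng(seed)
    exact = 0
    for _ in range(n_triples):
        p = rng.uniform(0.05, 0.6)
        masks = {e: rng.random(shape) < p for e in ("A", "B", "C")}
        stack = np.stack(list(masks.values()))
        coverage = stack.sum(axis=0)  # independent per-pixel enumeration
        tot = total_area(masks)
        uniq = {e: unique_area(masks, e) for e in masks}
        over = overlap_area(masks)
        ok = tot == sum(uniq.values()) + over
        ok &= tot == int((coverage >= 1).sum())
        ok &= over == int((coverage >= 2).sum())
        for i, e in enumerate(masks):
            ok &= uniq[e] == int((stack[i] & (coverage == 1)).sum())
        exact += bool(ok)
    return {"n": n_triples, "exact_fraction": exact / n_triples}


# ---------------------------------------------------------------------------
# 2. Otsu oracle equivalence


def _brute_force_otsu(values: np.ndarray, n_bins: int = 256) -> float:
    counts, edges = np.histogram(values, bins=n_bins, range=(values.min(), values.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    best_t, best_var = None, -1.0
    for t in range(n_bins - 1):
        n0 = counts[: t + 1].sum()
        n1 = counts[t + 1 :].sum()
        if n0 == 0 or n1 == 0:
            continue
        mu0 = (counts[: t + 1] * centers[: t + 1]).sum() / n0
        mu1 = (counts[t + 1 :] * centers[t + 1 :]).sum() / n1
        var = n0 * n1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return float(edges[best_t + 1])


def otsu_oracle_agreement(n_images: int = 500, seed: int = 0) -> dict:
    """Fraction of random 8-bit images where Otsu equals the exhaustive maximiser."""
    rng = np.random.default_rng(seed)
    agree = 0
    n_used = 0
    for _ in range(n_images):
        # mixture of two bands to make the histogram non-trivial
        lo = rng.integers(0, 120)
        hi = rng.integers(lo + 10, 256)
        img = np.where(
            rng.random((32, 32)) < rng.uniform(0.2, 0.8),
            rng.integers(0, lo + 1, size=(32, 32)),
            rng.integers(lo, hi + 1, size=(32, 32)),
        ).astype(float)
        if img.min() == img.max():
            continue
        n_used += 1
        agree += otsu_threshold(img) == _brute_force_otsu(img.ravel())
    return {"n": n_used, "agreement_fraction": agree / n_used}


# ---------------------------------------------------------------------------
# 3. ground-truth recovery


def _segment_all(image, config):
    return {
        e: segment_channel(ch, config, epitope=e, region_mask=image.region_mask)
        for e, ch in image.channels.items()
    }


def ground_truth_recovery(
    n_scenes: int = 20, seed: int = 0, noise_sigma: float = 2.0, config=None
) -> dict:
    """Pipeline percentage decomposition vs the exact expected report."""
    config = config or AnalysisConfig()
    max_err = 0.0
    jaccards = []
    for i in range(n_scenes):
        spec = scenes.random_scene(seed=seed + i, noise_sigma=noise_sigma)
        image, gt = scenes.render_scene(spec)
        expected = scenes.expected_report(gt)
        masks = _segment_all(image, config)
        got = epitope_report(masks, pixel_size_um=image.pixel_size_um)
        pairs = [(got.overlap_pct, expected.overlap_pct)]
        pairs += [(got.unique_pct[e], expected.unique_pct[e]) for e in image.epitopes]
        for g, x in pairs:
            max_err = max(max_err, abs(g - x))
        for e in image.epitopes:
            truth = gt.channel_mask(e)
            union = (masks[e].mask | truth).sum()
            if union:
                jaccards.append((masks[e].mask & truth).sum() / union)
    return {
        "n": n_scenes,
        "max_pct_error": float(max_err),
        "min_jaccard": float(min(jaccards)),
        "mean_jaccard": float(np.mean(jaccards)),
    }


# ---------------------------------------------------------------------------
# 4. morphology recovery


def morphology_recovery(n_scenes: int = 10, seed: int = 0, config=None) -> dict:
    """Noise-free classification and area-share recovery vs simulator kinds."""
    config = config or AnalysisConfig()
    n_correct = n_total = 0
    share_errs = []
    for i in range(n_scenes):
        spec = scenes.random_scene(seed=seed + i, noise_sigma=0.0)
        image, gt = scenes.render_scene(spec)
        masks = _segment_all(image, config)
        union = np.zeros(image.shape, bool)
        for cm in masks.values():
            union |= cm.mask
        objects = label_aggregates(union, image.pixel_size_um, config.min_object_px)
        truth_areas = {c: 0 for c in set(EXPECTED_CLASS.values())}
        gt_union_by_agg = []
        for agg_masks in gt.aggregate_masks:
            m = np.zeros(image.shape, bool)
            for arr in agg_masks.values():
                m |= arr
            gt_union_by_agg.append(m)
        for kind, m in zip(gt.kinds, gt_union_by_agg):
            truth_areas[EXPECTED_CLASS[kind]] += int(m.sum())
        for obj in objects:
            overlaps = [int((m & obj.footprint).sum()) for m in gt_union_by_agg]
            kind = gt.kinds[int(np.argmax(overlaps))]
            n_total += 1
            n_correct += obj.morph_class == EXPECTED_CLASS[kind]
        dist = morphology_distribution(objects)
        total_truth = sum(truth_areas.values())
        for c, a in truth_areas.items():
            share_errs.append(abs(dist.area_share_pct[c] - 100.0 * a / total_truth))
    return {
        "n_objects": n_total,
        "classification_rate": n_correct / n_total,
        "max_share_error_pct": float(max(share_errs)),
    }


# ---------------------------------------------------------------------------
# 5. PK parameter recovery and time-effect detection


PK_SCHEDULE = [0.0, 15.0, 30.0, 60.0]
PK_TRUTH = {15.0: 1.1, 30.0: 0.7, 60.0: 0.45}


def _pk_model(null: bool) -> scenes.PKModel:
    retention = {} if null else {"Nterm": dict(PK_TRUTH)}
    return scenes.PKModel(timepoints_min=list(PK_SCHEDULE), retention=retention)


def _measure_subject(seed: int, model: scenes.PKModel, config) -> dict[str, list[float]]:
    spec = scenes.pk_subject_spec(seed=seed)
    images, _ = scenes.simulate_pk_series(spec, model)
    union = np.zeros(images[0].shape, bool)
    for e, ch in images[0].channels.items():
        union |= segment_channel(ch, config, epitope=e).mask
    raw: dict[str, list[float]] = {}
    for img in images:
        for e, q in measure_timepoint(img, config, footprint=union, mode="intensity").items():
            raw.setdefault(e, []).append(q)
    return raw


def pk_recovery(n_subjects: int = 8, seed: int = 0, config=None) -> dict:
    """Estimated retention factors vs the simulated truth."""
    config = config or AnalysisConfig()
    model = _pk_model(null=False)
    errs = []
    estimates = {t: [] for t in PK_TRUTH}
    for s in range(n_subjects):
        raw = _measure_subject(seed * 1000 + s, model, config)
        series = normalize_series(f"s{s}", PK_SCHEDULE, raw)
        fit = fit_retention(series)["Nterm"]
        for t, truth in PK_TRUTH.items():
            got = fit.retention[PK_SCHEDULE.index(t)]
            estimates[t].append(got)
            errs.append(abs(got - truth))
        for e in ("pS129", "Cterm"):
            for r in fit_retention(series)[e].retention[1:]:
                errs.append(abs(r - 1.0))
    return {
        "n_subjects": n_subjects,
        "max_retention_error": float(max(errs)),
        "mean_retention": {str(t): float(np.mean(v)) for t, v in estimates.items()},
    }


def pk_time_effect_rates(
    n_replicates: int = 100, n_subjects: int = 8, seed: int = 0, alpha: float = 0.05,
    config=None,
) -> dict:
    """Repeated-measures ANOVA rejection rates under effect and null models."""
    config = config or AnalysisConfig()
    rates = {}
    for label, null in (("effect", False), ("null", True)):
        model = _pk_model(null=null)
        rejections = 0
        for r in range(n_replicates):
            table = []
            for s in range(n_subjects):
                raw = _measure_subject(seed + r * 1000 + s, model, config)
                series = normalize_series(f"s{s}", PK_SCHEDULE, raw)
                table.append(series.normalized_pct["Nterm"])
            res = rm_one_way_anova(np.asarray(table))
            rejections += res.p_value < alpha
        rates[label] = rejections / n_replicates
    return {"n_replicates": n_replicates, "rejection_rate": rates}


# ---------------------------------------------------------------------------
# 6. type-I calibration


def anova_type_i_rate(
    n_sims: int = 10_000, k: int = 3, n_per_group: int = 10, seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """One-way ANOVA rejection rate under the null (equal-mean normal groups)."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        groups = rng.normal(size=(k, n_per_group))
        rejections += one_way_anova(list(groups)).p_value < alpha
    return {"n": n_sims, "rejection_rate": rejections / n_sims}


# ---------------------------------------------------------------------------
# 7. complementary-cohort correlation


def cohort_correlation(n_cases: int = 23, seed: int = 0, config=None) -> dict:
    """Pipeline Pearson r between unique N-terminus and pS129 percentages."""
    config = config or AnalysisConfig()
    xs, ys = [], []
    for spec in scenes.complementary_cohort_specs(n_cases=n_cases, seed=seed):
        image, _ = scenes.render_scene(spec)
        masks = _segment_all(image, config)
        rep = epitope_report(masks, pixel_size_um=image.pixel_size_um)
        xs.append(rep.unique_pct["Nterm"])
        ys.append(rep.unique_pct["pS129"])
    res = pearson(xs, ys)
    return {"n": n_cases, "pearson_r": res.statistic, "p_value": res.p_value}
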