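"""Monte-Carlo experiments for calibrating and validating the statistics.

These helpers drive the same building blocks as the full pipeline
(:class:`~fetalvol.observer.SegmentationSampler`, the agreement estimators)
at reduced problem sizes, for coverage / power / type-I-error experiments:

* :func:`icc_ci_coverage` — does the ICC(A,1) F-based 95% CI cover a known
  true ICC under a two-way random-effects model?
* :func:`bland_altman_coverage` — do ±1.96·SD limits contain ~95% of
  Gaussian differences?
* :func:`replicate_observer_studies` — repeated synthetic two-observer
  studies on spherical truths: per replicate, n subjects × 2 observers × 2
  repeats of simulated segmentations, interobserver Bland–Altman mean
  difference and paired-t p-value.

Sphere truths at radii of 6–10 voxels are used instead of full phantoms:
observer variability acts purely in mask space, so image formation and
refinement add nothing to these statistical questions while dominating the
run time.
"""

from __future__ import annotations

import numpy as np

from .agreement import PairedSeries, bland_altman, icc_estimate, paired_t
from .observer import ObserverModel, SegmentationSampler


def icc_ci_coverage(
    true_icc: float = 0.8,
    n_subjects: int = 25,
    n_reps: int = 1000,
    seed: int = 0,
    rater_var_frac: float = 0.05,
) -> float:
    """Fraction of replicates whose 95% CI covers the true ICC.

    Data follow ``x_ij = r_i + c_j + e_ij`` with variance components chosen
    so that between-subject variance / total = ``true_icc``; the small rater
    component defaults to 5% of total variance.
    """
    rng = np.random.default_rng([seed, 41])
    var_r = true_icc
    var_c = rater_var_frac
    var_e = 1.0 - var_r - var_c
    if var_e <= 0:
        raise ValueError("rater_var_frac too large for the requested true ICC")
    hits = 0
    for _ in range(n_reps):
        r = rng.normal(0, np.sqrt(var_r), size=(n_subjects, 1))
        c = rng.normal(0, np.sqrt(var_c), size=(1, 2))
        e = rng.normal(0, np.sqrt(var_e), size=(n_subjects, 2))
        x = 100.0 + r + c + e
        pairs = PairedSeries(
            subject_ids=[str(i) for i in range(n_subjects)],
            a=x[:, 0],
            b=x[:, 1],
            design="inter",
        )
        _, lo, hi = icc_estimate(pairs)
        hits += lo <= true_icc <= hi
    return hits / n_reps


def bland_altman_coverage(n: int = 10_000, sigma: float = 10.0, seed: int = 0) -> float:
    """Share of percentage differences falling inside the 1.96-SD limits."""
    rng = np.random.default_rng([seed, 42])
    d = rng.normal(0.0, sigma, size=n)
    base = 100.0
    pairs = PairedSeries(
        subject_ids=[str(i) for i in range(n)],
        a=base * (1 + d / 200.0),
        b=base * (1 - d / 200.0),
        design="inter",
    )
    ba = bland_altman(pairs)
    inside = (ba.diffs_pct >= ba.loa_lower_pct) & (ba.diffs_pct <= ba.loa_upper_pct)
    return float(inside.mean())


def _sphere(radius: float, pad: int = 6) -> np.ndarray:
    n = int(2 * np.ceil(radius) + 2 * pad + 1)
    c = (n - 1) / 2.0
    g = np.arange(n)
    xx, yy, zz = np.meshgrid(g, g, g, indexing="ij")
    return (xx - c) ** 2 + (yy - c) ** 2 + (zz - c) ** 2 <= radius**2


def replicate_observer_studies(
    model_a: ObserverModel,
    model_b: ObserverModel,
    n_subjects: int = 25,
    n_reps: int = 200,
    seed: int = 0,
    radii: tuple[float, ...] = (6.0, 6.5, 7.0, 7.5, 8.0, 8.5, 9.0, 9.5, 10.0),
) -> dict:
    """Repeat a two-observer interobserver study on spherical truths.

    Per replicate: every subject gets a sphere truth with a radius drawn from
    ``radii``; each observer segments it twice through the jitter/bias
    sampler; volumes are voxel counts (the agreement statistics are scale
    invariant).  Returns per-replicate interobserver mean percentage
    differences and paired-t p-values.
    """
    rng = np.random.default_rng([seed, 43])
    samplers = {}
    for model, tag in ((model_a, "a"), (model_b, "b")):
        for r in radii:
            samplers[(tag, r)] = SegmentationSampler(
                _sphere(r), model.scale_bias, model.jitter_sd
            )
    mean_diffs = np.empty(n_reps)
    p_values = np.empty(n_reps)
    for rep in range(n_reps):
        a_means = np.empty(n_subjects)
        b_means = np.empty(n_subjects)
        for s in range(n_subjects):
            r = radii[rng.integers(len(radii))]
            va = [samplers[("a", r)].sample(rng).sum() for _ in range(2)]
            vb = [samplers[("b", r)].sample(rng).sum() for _ in range(2)]
            a_means[s] = np.mean(va)
            b_means[s] = np.mean(vb)
        pairs = PairedSeries(
            subject_ids=[str(i) for i in range(n_subjects)],
            a=a_means,
            b=b_means,
            design="inter",
        )
        ba = bland_altman(pairs)
        _, p = paired_t(pairs)
        mean_diffs[rep] = ba.mean_diff_pct
        p_values[rep] = p
    return {
        "mean_diff_pct": mean_diffs,
        "p_values": p_values,
        "rejection_rate": float((p_values < 0.05).mean()),
    }


def theoretical_mean_diff_pct(volume_ratio: float) -> float:
    """Expected Bland–Altman % difference when b = ratio × a: 200(1−ρ)/(1+ρ)."""
    return 200.0 * (1.0 - volume_ratio) / (1.0 + volume_ratio)


def paired_t_type_i_error(
    n_subjects: int = 25,
    n_reps: int = 1000,
    seed: int = 0,
    jitter_sd: float = 1.0,
    radii: tuple[float, ...] = (6.0, 7.0, 8.0, 9.0, 10.0),
) -> float:
    """Rejection rate at alpha=0.05 for two identically-behaved observers."""
    model = ObserverModel(observer_id="a", jitter_sd=jitter_sd)
    res = replicate_observer_studies(
        model, model, n_subjects=n_subjects, n_reps=n_reps, seed=seed, radii=radii
    )
    return res["rejection_rate"]
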