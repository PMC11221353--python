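"""Gene coverage, saturation curves, and TPM: hand oracles and invariants."""

from __future__ import annotations

import numpy as np
import pytest

from ivtkit.coverage import (
    coverage_vs_cutoff,
    gene_read_counts,
    naive_tpm,
    round_robin,
    saturation_curve,
    tpm_correlation,
)
from ivtkit.errors import ConfigurationError, InputError, InsufficientDataError


def test_coverage_vs_cutoff_hand_counts():
    counts = {"g1": 12, "g2": 9, "g3": 0}
    out = coverage_vs_cutoff(counts, {"g1", "g2", "g3"}, [1, 10])
    assert list(out["fraction"]) == pytest.approx([2 / 3, 1 / 3])


def test_coverage_vs_cutoff_saturated_and_monotone():
    universe = {f"g{i}" for i in range(20)}
    full = {g: 50 for g in universe}
    out = coverage_vs_cutoff(full, universe, [1, 10, 50])
    assert (out["fraction"] == 1.0).all()
    rng = np.random.default_rng(3)
    skewed = {g: int(v) for g, v in zip(universe, rng.zipf(1.5, 20))}
    out = coverage_vs_cutoff(skewed, universe, [1, 2, 5, 10, 50])
    assert (np.diff(out["fraction"]) <= 0).all()


def test_coverage_vs_cutoff_validation():
    with pytest.raises(ConfigurationError):
        coverage_vs_cutoff({"g": 1}, set(), [1])
    with pytest.raises(ConfigurationError):
        coverage_vs_cutoff({"g": 1}, {"g"}, [5, 2])


def _zipf_labels(rng, n_reads, n_genes, s=1.2):
    w = np.arange(1, n_genes + 1, dtype=float) ** -s
    w /= w.sum()
    return [f"g{i}" for i in rng.choice(n_genes, size=n_reads, p=w)]


def test_saturation_self_coverage_reaches_one():
    rng = np.random.default_rng(1)
    labels = _zipf_labels(rng, 2000, 30)
    curve = saturation_curve(
        labels, {f"p{i}": list(labels) for i in range(5)},
        target_draw=2000, step=1000, repeats=5, seed=0,
    )
    assert curve.mean_proportion[0] == 0.0
    assert curve.mean_proportion[-1] == pytest.approx(1.0)


def test_saturation_disjoint_population_stays_zero():
    rng = np.random.default_rng(2)
    target = _zipf_labels(rng, 500, 10)
    population = {f"p{i}": [f"other{j}" for j in range(100)] for i in range(5)}
    curve = saturation_curve(target, population, target_draw=500, step=100,
                             repeats=3, seed=0)
    assert (curve.mean_proportion == 0.0).all()


def test_saturation_curve_matches_high_repeat_oracle():
    """Mean curve within Monte-Carlo error of an independent resampler with
    a 10x repeat budget."""
    rng = np.random.default_rng(7)
    samples = {name: _zipf_labels(rng, 1000, 40) for name in "abcde"}
    target = _zipf_labels(rng, 1000, 40)
    repeats = 30
    curve = saturation_curve(target, samples, target_draw=1000, step=500,
                             max_combined=4000, repeats=repeats, seed=11)

    # brute-force oracle: literal re-sampling with its own RNG, 10x repeats
    orng = np.random.default_rng(99)
    target_genes = set(target)  # target_draw == len(target): the full set
    arrs = {s: np.array(v, dtype=object) for s, v in samples.items()}
    sizes = curve.sample_sizes
    oracle = np.zeros((10 * repeats, len(sizes)))
    for r in range(10 * repeats):
        for i, size in enumerate(sizes):
            per = int(round(size / len(arrs)))
            genes = set()
            for arr in arrs.values():
                take = orng.choice(arr, size=min(per, len(arr)), replace=False)
                genes.update(take)
            oracle[r, i] = len(genes & target_genes) / len(target_genes)
    mc_se = oracle.std(axis=0, ddof=1) * np.sqrt(1 / repeats + 1 / (10 * repeats))
    diff = np.abs(curve.mean_proportion - oracle.mean(axis=0))
    assert (diff <= 4 * mc_se + 1e-12).all()
    # non-decreasing in expectation (tolerance for residual MC noise)
    assert (np.diff(curve.mean_proportion) >= -4 * mc_se[1:]).all()


def test_saturation_union_score_exceeds_one():
    rng = np.random.default_rng(5)
    target = _zipf_labels(rng, 300, 10)
    population = {"p": [f"extra{j}" for j in range(50)]}
    curve = saturation_curve(target, population, target_draw=300, step=50,
                             max_combined=50, repeats=2, seed=0, score="union")
    assert curve.mean_proportion[0] == pytest.approx(1.0)  # union with empty set
    assert curve.mean_proportion[-1] > 1.0


def test_round_robin_produces_one_curve_per_sample():
    rng = np.random.default_rng(8)
    samples = {name: _zipf_labels(rng, 200, 15) for name in ("s1", "s2", "s3")}
    curves = round_robin(samples, target_draw=200, step=100, max_combined=400,
                         repeats=2, seed=1)
    assert set(curves) == set(samples)
    for name, curve in curves.items():
        assert curve.target == name
        assert (curve.mean_proportion >= 0).all()
        assert (curve.mean_proportion <= 1).all()


def test_saturation_validation():
    with pytest.raises(InputError):
        saturation_curve([], {"p": ["g"]}, target_draw=10, step=5, repeats=1)
    with pytest.raises(InputError):
        saturation_curve(["g"], {}, target_draw=10, step=5, repeats=1)
    with pytest.raises(ConfigurationError):
        saturation_curve(["g"], {"p": ["g"]}, target_draw=1, step=1, repeats=0)


def test_tpm_normalization_and_length_scaling():
    assert naive_tpm({"t1": 7}, {"t1": 1000})["t1"] == pytest.approx(1e6)
    tpm = naive_tpm({"a": 10, "b": 10}, {"a": 1000, "b": 2000})
    assert tpm["a"] / tpm["b"] == pytest.approx(2.0)
    assert tpm["a"] + tpm["b"] == pytest.approx(1e6)


def test_tpm_conservation_and_scale_invariance():
    rng = np.random.default_rng(4)
    for _ in range(10):
        n = rng.integers(3, 50)
        counts = {f"t{i}": int(c) for i, c in enumerate(rng.integers(1, 500, n))}
        lengths = {t: float(l) for t, l in zip(counts, rng.integers(200, 5000, n))}
        tpm = naive_tpm(counts, lengths)
        assert abs(sum(tpm.values()) - 1e6) / 1e6 < 1e-9
        scaled = naive_tpm({t: 3 * c for t, c in counts.items()}, lengths)
        for t in counts:
            assert scaled[t] == pytest.approx(tpm[t])


def test_tpm_validation():
    with pytest.raises(InputError):
        naive_tpm({"t": 1}, {})
    with pytest.raises(InputError):
        naive_tpm({"t": 0}, {"t": 100})


def test_tpm_correlation_perfect_linear_and_null():
    a = {f"t{i}": float(v) for i, v in enumerate([5, 10, 20, 40, 80])}
    b = {t: 2 * v for t, v in a.items()}
    r2, n = tpm_correlation(a, b, log_transform=False)
    assert r2 == pytest.approx(1.0) and n == 5
    rng = np.random.default_rng(6)
    x = {f"t{i}": float(v) for i, v in enumerate(rng.random(3000))}
    y = {f"t{i}": float(v) for i, v in enumerate(rng.random(3000))}
    r2_null, _ = tpm_correlation(x, y, log_transform=False)
    assert r2_null < 0.01


def test_tpm_correlation_matches_textbook_pearson():
    xs = [1.0, 2.0, 4.0, 8.0, 16.0]
    ys = [2.0, 3.0, 9.0, 15.0, 30.0]
    a = {f"t{i}": x for i, x in enumerate(xs)}
    b = {f"t{i}": y for i, y in enumerate(ys)}
    x, y = np.array(xs), np.array(ys)
    r_hand = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
        ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
    )
    r2, _ = tpm_correlation(a, b, log_transform=False)
    assert r2 == pytest.approx(r_hand**2)


def test_tpm_correlation_requires_shared_transcripts():
    with pytest.raises(InsufficientDataError):
        tpm_correlation({"a": 1.0, "b": 2.0}, {"b": 1.0, "c": 2.0})


def test_gene_read_counts_from_mapping_and_sequence():
    assert gene_read_counts(["g1", "g1", "g2"]) == {"g1": 2, "g2": 1}
    assert gene_read_counts({"r1": "g1", "r2": "g1"}) == {"g1": 2}
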