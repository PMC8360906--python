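"""Synthetic pseudo-experiment generators."""

import numpy as np
import pytest
from scipy import stats

from epistrain import SyntheticConfig, fit_kelvin_voigt, synth_divisions, synth_recoil
from epistrain.shape import division_rate, rose_histogram
from epistrain.synthetic import RecoilParams, recoil_traces_from_frame


@pytest.fixture(scope="module")
def config():
    return SyntheticConfig(master_seed=42)


def test_recoil_generator_roundtrip_noiseless():
    cfg = SyntheticConfig(
        master_seed=1, recoil=RecoilParams(noise_sigma=0.0, n_traces=2)
    )
    df = synth_recoil(cfg, groups={"kRasV12": 2.0})
    traces = recoil_traces_from_frame(df)
    for tr in traces:
        fit = fit_kelvin_voigt(tr)
        assert fit.asymptote_gain == pytest.approx(2.0 * cfg.recoil.amplitude, abs=1e-6)
        assert fit.rate_k == pytest.approx(cfg.recoil.rate, abs=1e-6)


def test_recoil_generator_deterministic(config):
    df1 = synth_recoil(config)
    df2 = synth_recoil(config)
    assert df1.to_csv(index=False) == df2.to_csv(index=False)


def test_recoil_noise_scales_residuals():
    rms = {}
    for sigma in (0.05, 0.10):
        cfg = SyntheticConfig(
            master_seed=5,
            recoil=RecoilParams(noise_sigma=sigma, n_traces=30),
        )
        df = synth_recoil(cfg, groups={"g": 1.0})
        resid = []
        for tr in recoil_traces_from_frame(df):
            fit = fit_kelvin_voigt(tr)
            resid.append(fit.residual_rms)
        rms[sigma] = np.mean(resid)
    assert rms[0.10] == pytest.approx(2 * rms[0.05], rel=0.25)


def test_division_poisson_mean_and_rate(config):
    """Expected event count matches rate * cells * duration."""
    totals = []
    for ms in range(30):
        cfg = SyntheticConfig(master_seed=ms)
        _, table = synth_divisions(cfg)
        totals.append(len(table))
    mean = np.mean(totals)  # Poisson mean 0.2/100% * 100 cells * 30 min = 6
    assert abs(mean - 6.0) < 3 * np.sqrt(6.0 / 30)
    cdr = division_rate(int(np.sum(totals)), 100 * 30, 30.0)
    assert cdr == pytest.approx(0.2, rel=0.25)


def test_division_angles_uniform_when_unbiased():
    from epistrain.shape import cluster_boundary, division_orientation

    angles = []
    for ms in range(25):
        cfg = SyntheticConfig(master_seed=ms)
        events, _ = synth_divisions(cfg)
        t = np.linspace(0, 2 * np.pi, 90, endpoint=False)
        boundary = cluster_boundary([np.stack([np.cos(t), np.sin(t)], axis=1)])
        angles.extend(division_orientation(e, boundary) for e in events)
    # kappa = 0: flat rose histogram within multinomial error
    counts = rose_histogram(angles)
    p = stats.chisquare(counts).pvalue
    assert p > 0.01
    assert stats.kstest(np.array(angles) / 90.0, "uniform").pvalue > 0.01


def test_division_angles_concentrate_with_kappa():
    from epistrain.synthetic import DivisionParams

    cfg = SyntheticConfig(
        master_seed=9,
        divisions=DivisionParams(kappa=10.0, rate_percent_per_min=2.0),
    )
    events, table = synth_divisions(cfg)
    from epistrain.shape import cluster_boundary, division_orientation

    t = np.linspace(0, 2 * np.pi, 90, endpoint=False)
    boundary = cluster_boundary([np.stack([np.cos(t), np.sin(t)], axis=1)])
    angles = np.array([division_orientation(e, boundary) for e in events])
    assert (angles <= 30).mean() > 0.5


def test_division_axes_unit_norm(config):
    _, table = synth_divisions(config)
    if len(table):
        norms = np.hypot(table["axis_x"], table["axis_y"])
        assert np.allclose(norms, 1.0)


def test_tracing_generator_deterministic_bytes():
    from epistrain.synthetic import synth_tracings

    cfg = SyntheticConfig(
        true_increment=0.0, n_pseudo_embryos=1, n_cells=60, cluster_size=7,
        master_seed=3,
    )
    csv1 = synth_tracings(cfg).to_csv(index=False)
    csv2 = synth_tracings(cfg).to_csv(index=False)
    assert csv1 == csv2
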