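"""Kelvin-Voigt recoil fitting."""

import numpy as np
import pytest

from epistrain import RecoilTrace, fit_kelvin_voigt, initial_recoil_summary
from epistrain.errors import ValidationError


def make_trace(d0=10.0, D=2.0, k=0.5, dt=4.0, n=15, noise=0.0, rng=None, **kw):
    t = np.concatenate([[-2 * dt, -dt], dt * np.arange(n)])
    d = np.where(t < 0, d0, d0 + D * (1 - np.exp(-k * np.maximum(t, 0))))
    if noise:
        d = d + rng.normal(0, noise, t.shape)
    return RecoilTrace(time_s=t, distance=d, **kw)


def test_noiseless_recovery_and_initial_recoil_identity():
    fit = fit_kelvin_voigt(make_trace(d0=10, D=2, k=0.5))
    assert fit.asymptote_gain == pytest.approx(2.0, abs=1e-6)
    assert fit.rate_k == pytest.approx(0.5, abs=1e-6)
    assert fit.initial_recoil == pytest.approx(1.0, abs=1e-6)
    assert fit.initial_recoil == fit.asymptote_gain * fit.rate_k
    assert fit.residual_rms < 1e-9


def test_constant_trace_gives_zero_recoil():
    fit = fit_kelvin_voigt(make_trace(D=0.0))
    assert abs(fit.asymptote_gain) < 1e-8
    assert abs(fit.initial_recoil) < 1e-8


def test_negative_amplitude_flagged():
    fit = fit_kelvin_voigt(make_trace(D=-1.5))
    assert fit.negative_amplitude
    assert fit.asymptote_gain == pytest.approx(-1.5, abs=1e-6)


def test_free_baseline_mode_recovers_d0():
    fit = fit_kelvin_voigt(make_trace(d0=7.3, D=2, k=0.5), fit_baseline=True)
    assert fit.baseline_distance == pytest.approx(7.3, abs=1e-6)
    assert fit.rate_k == pytest.approx(0.5, abs=1e-5)


def test_time_shift_invariance_after_reanchoring():
    """Extra pre-ablation frames do not change the fitted (D, k)."""
    base = make_trace()
    t_ext = np.concatenate([[-16.0, -12.0], base.time_s])
    d_ext = np.concatenate([[10.0, 10.0], base.distance])
    ext = RecoilTrace(time_s=t_ext, distance=d_ext)
    f1, f2 = fit_kelvin_voigt(base), fit_kelvin_voigt(ext)
    assert f1.asymptote_gain == pytest.approx(f2.asymptote_gain, abs=1e-9)
    assert f1.rate_k == pytest.approx(f2.rate_k, abs=1e-9)


def test_distance_rescaling_scales_amplitude_not_k():
    t1 = make_trace()
    t3 = RecoilTrace(time_s=t1.time_s, distance=3.0 * t1.distance)
    f1, f3 = fit_kelvin_voigt(t1), fit_kelvin_voigt(t3)
    assert f3.asymptote_gain == pytest.approx(3 * f1.asymptote_gain, rel=1e-9)
    assert f3.initial_recoil == pytest.approx(3 * f1.initial_recoil, rel=1e-9)
    assert f3.rate_k == pytest.approx(f1.rate_k, rel=1e-9)


def test_k_recovery_under_noise(rng):
    """Median relative error of k stays below 10% at 5% amplitude noise,
    at the synthetic defaults (k = 0.1/s resolved by 4 s frames)."""
    errs = []
    for _ in range(100):
        tr = make_trace(D=2.0, k=0.1, n=16, noise=0.05 * 2.0, rng=rng)
        fit = fit_kelvin_voigt(tr)
        errs.append(abs(fit.rate_k - 0.1) / 0.1)
    assert np.median(errs) < 0.10


def test_trace_validation():
    with pytest.raises(ValidationError, match="increasing"):
        RecoilTrace(time_s=[-4.0, 0, 4, 4, 8, 12, 16], distance=np.zeros(7))
    with pytest.raises(ValidationError, match="post-ablation"):
        RecoilTrace(time_s=[-4.0, 0, 4], distance=np.zeros(3))
    with pytest.raises(ValidationError, match="pre-ablation"):
        RecoilTrace(time_s=[0.0, 4, 8, 12, 16], distance=np.zeros(5))


def test_initial_recoil_summary_arithmetic():
    fits = [
        fit_kelvin_voigt(make_trace(D=D, k=0.5, group="g"))
        for D in (2.0, 4.0, 6.0)
    ]
    summary = initial_recoil_summary(fits)
    row = summary[summary.group == "g"].iloc[0]
    # initial recoils are {1, 2, 3}: mean 2, sem = sd/sqrt(3) = 1/sqrt(3)
    assert row["n"] == 3
    assert row["initial_recoil_mean"] == pytest.approx(2.0, abs=1e-6)
    assert row["initial_recoil_sem"] == pytest.approx(1 / np.sqrt(3), abs=1e-6)
    single = initial_recoil_summary(fits[:1])
    assert np.isnan(single.iloc[0]["initial_recoil_sem"])
    two_same = initial_recoil_summary(
        [fit_kelvin_voigt(make_trace(group="h")) for _ in range(2)]
    )
    assert two_same.iloc[0]["initial_recoil_sem"] == pytest.approx(0.0, abs=1e-9)
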