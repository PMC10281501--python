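import numpy as np
import pytest

from salmoscope import simulate
from salmoscope.bayes import SamplerConfig


@pytest.fixture(scope="session")
def small_cohort():
    """Three populations at reduced sample sizes: fast but structured like
    the full design."""
    return simulate.CohortConfig(
        populations=("Coleman", "Priest Rapids", "Trask River"),
        ctmax_n_range=(14, 16), resp_n_range=(20, 24), growth_n_per_date=15,
        test_temps=(8.0, 12.0, 16.0, 20.0, 24.0, 26.0),
    )


@pytest.fixture(scope="session")
def small_truth(small_cohort):
    return simulate.default_truth(small_cohort, seed=0)


@pytest.fixture(scope="session")
def fast_sampler():
    return SamplerConfig(draws=500, warmup=300)


def make_trace(mo2, mass_kg=0.024, volume_L=5.0, alpha=0.0563, bp=760.0,
               period_s=900, n_periods=3, flush_s=240, start_sat=100.0,
               noise_sd=0.0, seed=0, context="routine"):
    """Hand-built trace with each sealed period depleting at the rate implied
    by mo2 (a scalar or one value per period)."""
    from salmoscope.respirometry import MeasurePeriod, O2Trace

    rng = np.random.default_rng(seed)
    mo2 = np.broadcast_to(np.asarray(mo2, float), (n_periods,))
    times, sats, phases = [], [], []
    t = 0.0
    for k in range(n_periods):
        slope = -mo2[k] * mass_kg / (volume_L * 60.0) / (alpha * bp / 100.0)
        tt = t + np.arange(period_s)
        sats.append(start_sat + slope * (tt - t))
        times.append(tt)
        phases.append(MeasurePeriod(tt[0], tt[-1], "sealed", context,
                                    30.0 if context == "swim" else 0.0))
        t = tt[-1] + 1
        tt = t + np.arange(flush_s)
        times.append(tt)
        sats.append(np.full(flush_s, start_sat))
        phases.append(MeasurePeriod(tt[0], tt[-1], "flush", "routine", 0.0))
        t = tt[-1] + 1
    tt = np.concatenate(times)
    ss = np.concatenate(sats) + rng.normal(0, noise_sd, t and len(tt))
    return O2Trace(fish_id="T", test_temp_C=16.0, acclim_temp_C=16.0,
                   tunnel_id="S1", tunnel_volume_L=volume_L, fish_mass_kg=mass_kg,
                   barometric_pressure_mmHg=bp, alpha_O2=alpha,
                   samples=np.column_stack([tt, np.clip(ss, 0, 110)]),
                   phases=phases)
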