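import numpy as np
import pandas as pd
import pytest

import tremorlab as tl
from tremorlab.pipeline import metrics_wide
from tremorlab.spectral import metrics_for_record

#: One fixed seed for every stochastic fixture/test in the suite.
SUITE_SEED = 20110510


@pytest.fixture(scope="session")
def spec128():
    return tl.SignalSpec(sampling_rate=128.0, duration=16.0)


@pytest.fixture(scope="session")
def simulated_cohort_wide():
    """200 subjects per archetype group, rendered and measured end-to-end.

    One row per subject: group labels, demographics, realized targets and
    the estimated ``{condition}_{side}_{metric}`` columns.  Shared by the
    moment-recovery and classifier tests.
    """
    spec = tl.SignalSpec()
    profiles, records = tl.simulate_cohort((200, 200, 200), spec, seed=SUITE_SEED)
    rows = [
        {
            "subject_id": r.subject_id,
            "condition": r.condition,
            "side": r.side,
            **metrics_for_record(r).as_dict(),
        }
        for r in records
    ]
    return metrics_wide(pd.DataFrame(rows), tl.cohort_frame(profiles))


def band_limited_rms(x: np.ndarray, fs: float, band=tl.BAND) -> float:
    """Independent time-domain oracle: zero-phase Butterworth band-pass
    followed by sample RMS.

    A long linear-phase FIR band-pass keeps the passband flat to well
    under 1% (an IIR design is several dB down at its cutoffs, which would
    bias the oracle for signals touching the band edges).
    """
    from scipy.signal import filtfilt, firwin

    taps = firwin(801, [band[0], band[1]], pass_zero=False, fs=fs)
    y = filtfilt(taps, 1.0, x, padlen=min(1000, len(x) - 1))
    return float(np.sqrt(np.mean(y**2)))


def brute_force_dispersion(freqs, power, median, frac=0.68):
    """Exhaustive symmetric-window search oracle for frequency dispersion."""
    total = power.sum()
    dists = np.abs(freqs - median)
    best = None
    for w in np.unique(dists):
        if power[dists <= w + 1e-9].sum() >= frac * total:
            best = 2 * w
            break
    return best
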