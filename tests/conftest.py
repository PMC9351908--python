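import numpy as np
import pytest

from fibwave.esaf import esaf_cancel
from fibwave.preprocessing import build_impulse_train, detect_r_peaks, wavelet_bandlimit
from fibwave.synthetic import FWaveParams, NoiseSpec, gen_af_ecg

FS = 2000.0


@pytest.fixture(scope="session")
def fs():
    return FS


@pytest.fixture(scope="session")
def clean_epoch():
    """Synthetic AF epoch with white noise only (10 uV RMS), V1 f-wave
    planted at 70 uV peak-to-trough, plus its ground truth."""
    fwp = {"V1": FWaveParams(peak_to_peak=70.0, seed=321)}
    epoch, truth = gen_af_ecg(
        fwave_params=fwp,
        noise=NoiseSpec(baseline_rms=0.0, powerline_rms=0.0, white_rms=10.0, seed=99),
        seed=3,
    )
    return epoch, truth


@pytest.fixture(scope="session")
def cancelled_v1(clean_epoch):
    """Band-limited lead V1 of the clean epoch after QRST cancellation."""
    epoch, truth = clean_epoch
    filt = wavelet_bandlimit(epoch.lead("V1"), epoch.fs)
    ref = wavelet_bandlimit(epoch.lead("II"), epoch.fs)
    peaks = detect_r_peaks(ref, epoch.fs)
    train = build_impulse_train(peaks, epoch.n_samples)
    atr = esaf_cancel(filt, train, lead="V1")
    return atr, truth


def rms(x):
    return float(np.sqrt(np.mean(np.square(x))))
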