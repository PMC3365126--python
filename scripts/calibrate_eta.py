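"""Calibrate the default viscoelastic coefficient eta.

The published optimal eta display is not available, so the default is
chosen as the value that makes the normalized isometric force amplitude
flattest (least-squares in log space) over 1-80 kHz with nu = 0.7 and all
other defaults fixed.  Run from the repository root:

    python scripts/calibrate_eta.py
"""

import numpy as np
from scipy.optimize import minimize_scalar

from prestinmem.frequency_response import isometric_force
from prestinmem.parameters import default_ohc_params


def main() -> None:
    p0 = default_ohc_params()
    omega = 2 * np.pi * np.logspace(3, np.log10(8e4), 200)

    def flatness(log_eta: float) -> float:
        p = p0.replace(eta=float(np.exp(log_eta)))
        return float(np.sum(np.log(isometric_force(p, omega).amplitude_norm) ** 2))

    res = minimize_scalar(
        flatness, bounds=(np.log(1e-7), np.log(1e-3)), method="bounded"
    )
    eta = float(np.exp(res.x))
    amp = isometric_force(p0.replace(eta=eta), omega).amplitude_norm
    print(f"calibrated eta = {eta:.4g} N s^nu / m")
    print(f"amplitude band over 1-80 kHz: [{amp.min():.4f}, {amp.max():.4f}]")
    print(f"frozen default: {p0.eta:.4g}")


if __name__ == "__main__":
    main()
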