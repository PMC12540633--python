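"""Sixth-order polynomial approximation of the Universal Thermal Climate Index.

The operational UTCI procedure approximates the equivalent temperature of the
Fiala multi-node thermoregulation model by a polynomial in four variables:
air temperature ``ta`` [degC], wind speed at 10 m ``va`` [m/s], the radiant
excess ``d_tmrt = tmrt - ta`` [K], and water vapour pressure ``pa`` [kPa].
All 210 published coefficients are transcribed below; the function is a plain
elementwise expression and therefore works on scalars and numpy arrays alike.

Validity box of the approximation: ta in [-50, 50] degC, d_tmrt in [-30, 70] K,
va in [0.5, 17] m/s, pa below saturation (and <= 5 kPa). Clamping to this box
is the caller's responsibility (see :mod:`heatwalk.microclimate`).
"""

from __future__ import annotations

import numpy as np

__all__ = ["utci_offset", "utci_approx"]


def utci_offset(ta, va, d_tmrt, pa):
    """Polynomial offset such that ``UTCI = ta + utci_offset(...)``.

    Parameters are air temperature [degC], 10-m wind speed [m/s], mean radiant
    temperature minus air temperature [K], and vapour pressure [kPa].
    """
    ta = np.asarray(ta, dtype=float)
    va = np.asarray(va, dtype=float)
    d = np.asarray(d_tmrt, dtype=float)
    pa = np.asarray(pa, dtype=float)

    ta2 = ta * ta
    ta3 = ta2 * ta
    ta4 = ta3 * ta
    ta5 = ta4 * ta
    ta6 = ta5 * ta
    va2 = va * va
    va3 = va2 * va
    va4 = va3 * va
    va5 = va4 * va
    va6 = va5 * va
    d2 = d * d
    d3 = d2 * d
    d4 = d3 * d
    d5 = d4 * d
    d6 = d5 * d
    pa2 = pa * pa
    pa3 = pa2 * pa
    pa4 = pa3 * pa
    pa5 = pa4 * pa
    pa6 = pa5 * pa

    off = (
        6.07562052e-01
        + -2.27712343e-02 * ta
        + 8.06470249e-04 * ta2
        + -1.54271372e-04 * ta3
        + -3.24651735e-06 * ta4
        + 7.32602852e-08 * ta5
        + 1.35959073e-09 * ta6
        + -2.25836520e00 * va
        + 8.80326035e-02 * ta * va
        + 2.16844454e-03 * ta2 * va
        + -1.53347087e-05 * ta3 * va
        + -5.72983704e-07 * ta4 * va
        + -2.55090145e-09 * ta5 * va
        + -7.51269505e-01 * va2
        + -4.08350271e-03 * ta * va2
        + -5.21670675e-05 * ta2 * va2
        + 1.94544667e-06 * ta3 * va2
        + 1.14099531e-08 * ta4 * va2
        + 1.58137256e-01 * va3
        + -6.57263143e-05 * ta * va3
        + 2.22697524e-07 * ta2 * va3
        + -4.16117031e-08 * ta3 * va3
        + -1.27762753e-02 * va4
        + 9.66891875e-06 * ta * va4
        + 2.52785852e-09 * ta2 * va4
        + 4.56306672e-04 * va5
        + -1.74202546e-07 * ta * va5
        + -5.91491269e-06 * va6
        + 3.98374029e-01 * d
        + 1.83945314e-04 * ta * d
        + -1.73754510e-04 * ta2 * d
        + -7.60781159e-07 * ta3 * d
        + 3.77830287e-08 * ta4 * d
        + 5.43079673e-10 * ta5 * d
        + -2.00518269e-02 * va * d
        + 8.92859837e-04 * ta * va * d
        + 3.45433048e-06 * ta2 * va * d
        + -3.77925774e-07 * ta3 * va * d
        + -1.69699377e-09 * ta4 * va * d
        + 1.69992415e-04 * va2 * d
        + -4.99204314e-05 * ta * va2 * d
        + 2.47417178e-07 * ta2 * va2 * d
        + 1.07596466e-08 * ta3 * va2 * d
        + 8.49242932e-05 * va3 * d
        + 1.35191328e-06 * ta * va3 * d
        + -6.21531254e-09 * ta2 * va3 * d
        + -4.99410301e-06 * va4 * d
        + -1.89489258e-08 * ta * va4 * d
        + 8.15300114e-08 * va5 * d
        + 7.55043090e-04 * d2
        + -5.65095215e-05 * ta * d2
        + -4.52166564e-07 * ta2 * d2
        + 2.46688878e-08 * ta3 * d2
        + 2.42674348e-10 * ta4 * d2
        + 1.54547250e-04 * va * d2
        + 5.24110970e-06 * ta * va * d2
        + -8.75874982e-08 * ta2 * va * d2
        + -1.50743064e-09 * ta3 * va * d2
        + -1.56236307e-05 * va2 * d2
        + -1.33895614e-07 * ta * va2 * d2
        + 2.49709824e-09 * ta2 * va2 * d2
        + 6.51711721e-07 * va3 * d2
        + 1.94960053e-09 * ta * va3 * d2
        + -1.00361113e-08 * va4 * d2
        + -1.21206673e-05 * d3
        + -2.18203660e-07 * ta * d3
        + 7.51269482e-09 * ta2 * d3
        + 9.79063848e-11 * ta3 * d3
        + 1.25006734e-06 * va * d3
        + -1.81584736e-09 * ta * va * d3
        + -3.52197671e-10 * ta2 * va * d3
        + -3.36514630e-08 * va2 * d3
        + 1.35908359e-10 * ta * va2 * d3
        + 4.17032620e-10 * va3 * d3
        + -1.30369025e-09 * d4
        + 4.13908461e-10 * ta * d4
        + 9.22652254e-12 * ta2 * d4
        + -5.08220384e-09 * va * d4
        + -2.24730961e-11 * ta * va * d4
        + 1.17139133e-10 * va2 * d4
        + 6.62154879e-10 * d5
        + 4.03863260e-13 * ta * d5
        + 1.95087203e-12 * va * d5
        + -4.73602469e-12 * d6
        + 5.12733497e00 * pa
        + -3.12788561e-01 * ta * pa
        + -1.96701861e-02 * ta2 * pa
        + 9.99690870e-04 * ta3 * pa
        + 9.51738512e-06 * ta4 * pa
        + -4.66426341e-07 * ta5 * pa
        + 5.48050612e-01 * va * pa
        + -3.30552823e-03 * ta * va * pa
        + -1.64119440e-03 * ta2 * va * pa
        + -5.16670694e-06 * ta3 * va * pa
        + 9.52692432e-07 * ta4 * va * pa
        + -4.29223622e-02 * va2 * pa
        + 5.00845667e-03 * ta * va2 * pa
        + 1.00601257e-06 * ta2 * va2 * pa
        + -1.81748644e-06 * ta3 * va2 * pa
        + -1.25813502e-03 * va3 * pa
        + -1.79330391e-04 * ta * va3 * pa
        + 2.34994441e-06 * ta2 * va3 * pa
        + 1.29735808e-04 * va4 * pa
        + 1.29064870e-06 * ta * va4 * pa
        + -2.28558686e-06 * va5 * pa
        + -3.69476348e-02 * d * pa
        + 1.62325322e-03 * ta * d * pa
        + -3.14279680e-05 * ta2 * d * pa
        + 2.59835559e-06 * ta3 * d * pa
        + -4.77136523e-08 * ta4 * d * pa
        + 8.64203390e-03 * va * d * pa
        + -6.87405181e-04 * ta * va * d * pa
        + -9.13863872e-06 * ta2 * va * d * pa
        + 5.15916806e-07 * ta3 * va * d * pa
        + -3.59217476e-05 * va2 * d * pa
        + 3.28696511e-05 * ta * va2 * d * pa
        + -7.10542454e-07 * ta2 * va2 * d * pa
        + -1.24382300e-05 * va3 * d * pa
        + -7.38584400e-09 * ta * va3 * d * pa
        + 2.20609296e-07 * va4 * d * pa
        + -7.32469180e-04 * d2 * pa
        + -1.87381964e-05 * ta * d2 * pa
        + 4.80925239e-06 * ta2 * d2 * pa
        + -8.75492040e-08 * ta3 * d2 * pa
        + 2.77862930e-05 * va * d2 * pa
        + -5.06004592e-06 * ta * va * d2 * pa
        + 1.14325367e-07 * ta2 * va * d2 * pa
        + 2.53016723e-06 * va2 * d2 * pa
        + -1.72857035e-08 * ta * va2 * d2 * pa
        + -3.95079398e-08 * va3 * d2 * pa
        + -3.59413173e-07 * d3 * pa
        + 7.04388046e-07 * ta * d3 * pa
        + -1.89309167e-08 * ta2 * d3 * pa
        + -4.79768731e-07 * va * d3 * pa
        + 7.96079978e-09 * ta * va * d3 * pa
        + 1.62897058e-09 * va2 * d3 * pa
        + 3.94367674e-08 * d4 * pa
        + -1.18566247e-09 * ta * d4 * pa
        + 3.34678041e-10 * va * d4 * pa
        + -1.15606447e-10 * d5 * pa
        + -2.80626406e00 * pa2
        + 5.48712484e-01 * ta * pa2
        + -3.99428410e-03 * ta2 * pa2
        + -9.54009191e-04 * ta3 * pa2
        + 1.93090978e-05 * ta4 * pa2
        + -3.08806365e-01 * va * pa2
        + 1.16952364e-02 * ta * va * pa2
        + 4.95271903e-04 * ta2 * va * pa2
        + -1.90710882e-05 * ta3 * va * pa2
        + 2.10787756e-03 * va2 * pa2
        + -6.98445738e-04 * ta * va2 * pa2
        + 2.30109073e-05 * ta2 * va2 * pa2
        + 4.17856590e-04 * va3 * pa2
        + -1.27043871e-05 * ta * va3 * pa2
        + -3.04620472e-06 * va4 * pa2
        + 5.14507424e-02 * d * pa2
        + -4.32510997e-03 * ta * d * pa2
        + 8.99281156e-05 * ta2 * d * pa2
        + -7.14663943e-07 * ta3 * d * pa2
        + -2.66016305e-04 * va * d * pa2
        + 2.63789586e-04 * ta * va * d * pa2
        + -7.01199003e-06 * ta2 * va * d * pa2
        + -1.06823306e-04 * va2 * d * pa2
        + 3.61341136e-06 * ta * va2 * d * pa2
        + 2.29748967e-07 * va3 * d * pa2
        + 3.04788893e-04 * d2 * pa2
        + -6.42070836e-05 * ta * d2 * pa2
        + 1.16257971e-06 * ta2 * d2 * pa2
        + 7.68023384e-06 * va * d2 * pa2
        + -5.47446896e-07 * ta * va * d2 * pa2
        + -3.59937910e-08 * va2 * d2 * pa2
        + -4.36497725e-06 * d3 * pa2
        + 1.68737969e-07 * ta * d3 * pa2
        + 2.67489271e-08 * va * d3 * pa2
        + 3.23926897e-09 * d4 * pa2
        + -3.53874123e-02 * pa3
        + -2.21201190e-01 * ta * pa3
        + 1.55126038e-02 * ta2 * pa3
        + -2.63917279e-04 * ta3 * pa3
        + 4.53433455e-02 * va * pa3
        + -4.32943862e-03 * ta * va * pa3
        + 1.45389826e-04 * ta2 * va * pa3
        + 2.17508610e-04 * va2 * pa3
        + -6.66724702e-05 * ta * va2 * pa3
        + 3.33217140e-05 * va3 * pa3
        + -2.26921615e-03 * d * pa3
        + 3.80261982e-04 * ta * d * pa3
        + -5.45314314e-09 * ta2 * d * pa3
        + -7.96355448e-04 * va * d * pa3
        + 2.53458034e-05 * ta * va * d * pa3
        + -6.31223658e-06 * va2 * d * pa3
        + 3.02122035e-04 * d2 * pa3
        + -4.77403547e-06 * ta * d2 * pa3
        + 1.73825715e-06 * va * d2 * pa3
        + -4.09087898e-07 * d3 * pa3
        + 6.14155345e-01 * pa4
        + -6.16755931e-02 * ta * pa4
        + 1.33374846e-03 * ta2 * pa4
        + 3.55375387e-03 * va * pa4
        + -5.13027851e-04 * ta * va * pa4
        + 1.02449757e-04 * va2 * pa4
        + -1.48526421e-03 * d * pa4
        + -4.11469183e-05 * ta * d * pa4
        + -6.80434415e-06 * va * d * pa4
        + -9.77675906e-06 * d2 * pa4
        + 8.82773108e-02 * pa5
        + -3.01859306e-03 * ta * pa5
        + 1.04452989e-03 * va * pa5
        + 2.47090539e-04 * d * pa5
        + 1.48348065e-03 * pa6
    )
    return off


def utci_approx(ta, va, d_tmrt, pa):
    """UTCI [degC] = air temperature plus the polynomial offset (no clamping)."""
    return np.asarray(ta, dtype=float) + utci_offset(ta, va, d_tmrt, pa)
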