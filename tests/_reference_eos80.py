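"""Independent scalar reference of the UNESCO 1983 seawater polynomials.

Transliterated Fortran-style (Horner nesting, scalar only) from the published
coefficient tables, deliberately structured differently from the package
implementation so it can serve as a transcription cross-check oracle.
"""

def dens0(s, t):
    """Density at atmospheric pressure (kg/m3)."""
    b0, b1, b2, b3, b4 = 8.24493e-1, -4.0899e-3, 7.6438e-5, -8.2467e-7, 5.3875e-9
    c0, c1, c2 = -5.72466e-3, 1.0227e-4, -1.6546e-6
    d0 = 4.8314e-4
    a0, a1, a2 = 999.842594, 6.793952e-2, -9.095290e-3
    a3, a4, a5 = 1.001685e-4, -1.120083e-6, 6.536332e-9
    smow = a0 + t * (a1 + t * (a2 + t * (a3 + t * (a4 + t * a5))))
    return (
        smow
        + s * (b0 + t * (b1 + t * (b2 + t * (b3 + t * b4))))
        + s ** 1.5 * (c0 + t * (c1 + t * c2))
        + d0 * s * s
    )


def seck(s, t, p_dbar):
    """Secant bulk modulus; pressure input in dbar, used internally in bar."""
    p = p_dbar / 10.0
    h3, h2, h1, h0 = -5.77905e-7, 1.16092e-4, 1.43713e-3, 3.239908
    aw = h0 + t * (h1 + t * (h2 + t * h3))
    k2, k1, k0 = -1.6078e-6, -1.0981e-5, 2.2838e-3
    a = aw + s * (k0 + t * (k1 + t * k2)) + 1.91075e-4 * s ** 1.5
    m2, m1, m0 = 9.1697e-10, 2.0816e-8, -9.9348e-7
    b = 8.50935e-5 + t * (-6.12293e-6 + t * 5.2787e-8) + s * (m0 + t * (m1 + t * m2))
    e4, e3, e2, e1, e0 = -5.155288e-5, 1.360477e-2, -2.327105, 148.4206, 19652.21
    kw = e0 + t * (e1 + t * (e2 + t * (e3 + t * e4)))
    j0 = 1.91075e-4  # noqa: F841  (kept to mirror the published table layout)
    f3, f2, f1, f0 = -6.1670e-5, 1.09987e-2, -0.603459, 54.6746
    g2, g1, g0 = -5.3009e-4, 1.6483e-2, 7.944e-2
    kst0 = kw + s * (f0 + t * (f1 + t * (f2 + t * f3))) \
        + s ** 1.5 * (g0 + t * (g1 + t * g2))
    return kst0 + a * p + b * p * p


def dens(s, t, p_dbar):
    """In-situ density at pressure (kg/m3)."""
    rho0 = dens0(s, t)
    k = seck(s, t, p_dbar)
    p = p_dbar / 10.0
    return rho0 / (1.0 - p / k)


def atg(s, t, p):
    """Adiabatic lapse rate (deg C / dbar)."""
    ds = s - 35.0
    return (
        ((-2.1687e-16 * t + 1.8676e-14) * t - 4.6206e-13) * p * p
        + ((2.7759e-12 * t - 1.1351e-10) * ds
           + ((-5.4481e-14 * t + 8.733e-12) * t - 6.7795e-10) * t + 1.8741e-8) * p
        + (-4.2393e-8 * t + 1.8932e-6) * ds
        + ((6.6228e-10 * t - 6.836e-8) * t + 8.5258e-6) * t + 3.5803e-5
    )


def theta_fine(s, t, p, pr, n_steps=2000):
    """Potential temperature by fine-step RK4 integration of the lapse rate."""
    h = (pr - p) / n_steps
    tt, pp = t, p
    for _ in range(n_steps):
        k1 = atg(s, tt, pp)
        k2 = atg(s, tt + 0.5 * h * k1, pp + 0.5 * h)
        k3 = atg(s, tt + 0.5 * h * k2, pp + 0.5 * h)
        k4 = atg(s, tt + h * k3, pp + h)
        tt += h * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
        pp += h
    return tt


def sigma_theta_ref(s, t, p, n_steps=200):
    return dens0(s, theta_fine(s, t, p, 0.0, n_steps)) - 1000.0
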