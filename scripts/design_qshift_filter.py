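"""Regenerate the Q-shift filter frozen in dtseg.transform.QSHIFT_LOWPASS.

Design: an orthonormal even-length lowpass filter h whose group delay is
(N-1)/2 + 1/4 samples.  h is taken as the even-indexed samples of a
symmetric length-2N prototype p; shaping p as a sharp lowpass with cutoff
pi/4 makes the aliasing term in H(w) = (P(w/2) + P(w/2 - pi))/2 negligible,
so h inherits p's linear phase at half rate: delay (2N-1)/4.  Exact
conjugate-quadrature orthonormality and one vanishing moment are imposed as
equality constraints (trust-constr); the least-squares response objective is
quadratic in the prototype half.

Run:  python scripts/design_qshift_filter.py
Prints the 18 coefficients at full precision plus design diagnostics.
"""
import numpy as np
from scipy.optimize import NonlinearConstraint, minimize
from scipy.signal import firwin

N_TAPS = 18
PASS_EDGE = 0.20  # prototype passband edge, fraction of pi
STOP_EDGE = 0.30  # prototype stopband edge, fraction of pi
W_STOP = 10.0
W_STOP_DEEP = 40.0  # extra weight beyond pi/2 (controls the alias term)
RESTARTS = 40
SEED = 5


def half_to_filter(ph: np.ndarray) -> np.ndarray:
    p = np.concatenate([ph, ph[::-1]])
    return p[0::2]


def main() -> np.ndarray:
    n = N_TAPS
    alt = (-1.0) ** np.arange(n)
    wgrid = np.linspace(0.0, np.pi, 2048)
    # amplitude of the symmetric prototype: A(w) = 2 sum ph[m] cos(w(d - m))
    M = 2.0 * np.cos(np.outer(wgrid, (2 * n - 1) / 2.0 - np.arange(n)))
    pb = wgrid <= PASS_EDGE * np.pi
    sb = wgrid >= STOP_EDGE * np.pi
    sb_deep = wgrid >= 0.50 * np.pi

    def resp(ph):
        A = M @ ph
        return (
            np.mean((A[pb] - 2.0 * np.sqrt(2.0)) ** 2)
            + W_STOP * np.mean(A[sb] ** 2)
            + W_STOP_DEEP * np.mean(A[sb_deep] ** 2)
        )

    def cons_f(ph):
        h = half_to_filter(ph)
        c = [h @ h - 1.0, h @ alt]
        for k in range(1, n // 2):
            c.append(np.dot(h[: n - 2 * k], h[2 * k :]))
        return np.array(c)

    nlc = NonlinearConstraint(cons_f, 0.0, 0.0)
    rng = np.random.default_rng(SEED)
    p0 = firwin(2 * n, 0.25) * np.sqrt(2.0)
    best = None
    for trial in range(RESTARTS):
        x0 = p0[:n] + (0 if trial == 0 else rng.normal(0, 0.05, n))
        res = minimize(
            resp,
            x0,
            method="trust-constr",
            constraints=[nlc],
            options={"maxiter": 5000, "gtol": 1e-13, "xtol": 1e-16},
        )
        viol = np.max(np.abs(cons_f(res.x)))
        score = res.fun + 1e3 * max(0.0, viol - 1e-9)
        if best is None or score < best[0]:
            best = (score, res)
    h = half_to_filter(best[1].x)
    h = h / np.linalg.norm(h)
    if h.sum() < 0:
        h = -h

    # diagnostics
    w = np.linspace(1e-3, np.pi, 4096)
    H = np.exp(-1j * np.outer(w, np.arange(n))) @ h
    gd = -np.gradient(np.unwrap(np.angle(H)), w)
    pbm = w < 0.4 * np.pi
    sbm = w > 0.62 * np.pi
    print(f"# group delay {gd[pbm].mean():.4f} +/- {gd[pbm].std():.4f} "
          f"(target {(2 * n - 1) / 4})")
    print(f"# stopband max {20 * np.log10(np.abs(H[sbm]).max() / np.sqrt(2)):.1f} dB")
    print(f"# sum {h.sum():.12f}  H(pi) {h @ alt:.3e}")
    ac = max(abs(np.dot(h[: n - 2 * k], h[2 * k :])) for k in range(1, n // 2))
    print(f"# max even-lag autocorrelation {ac:.3e}")
    print("QSHIFT_LOWPASS = np.array([")
    for v in h:
        print(f"    {v!r},")
    print("])")
    return h


if __name__ == "__main__":
    main()
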