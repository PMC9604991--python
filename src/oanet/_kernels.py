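"""Numba-compiled integration kernels.

Both the mean-field model and the finite-N oscillator network use explicit
first-order Euler stepping with delayed coupling read from a dense complex
order-parameter history ``z[t, n]``.  Delays are pre-rounded to integer
multiples of the step size, so delayed values are plain array lookups.
The kernels are compiled with ``cache=True`` so the compilation cost is
paid once per machine.
"""

import numpy as np
from numba import njit

TWO_PI = 2.0 * np.pi


@njit(cache=True, fastmath=True)
def decoupled_history(r0, psi0, L, delta, om_rad, dt, depth, r_floor):
    """Evolve each ensemble independently (G = 0) to fill the delay buffer.

    Starts from (r0, psi0) at t = -(depth-1)*dt and steps to t = 0,
    storing z = r e^{i psi} at every step.  Returns (z_hist, r_t0, psi_t0).
    """
    E = r0.shape[0]
    z = np.empty((depth, E), np.complex128)
    r = r0.copy()
    psi = psi0.copy()
    for n in range(E):
        z[0, n] = r[n] * (np.cos(psi[n]) + 1j * np.sin(psi[n]))
    for k in range(1, depth):
        for n in range(E):
            rn = r[n]
            dr = -delta * rn + 0.5 * L[n] * (1.0 - rn * rn) * rn
            rn = rn + dt * dr
            if rn < r_floor:
                rn = r_floor
            elif rn > 1.0:
                rn = 1.0
            pn = psi[n] + dt * om_rad
            pn = (pn + np.pi) % TWO_PI - np.pi
            r[n] = rn
            psi[n] = pn
            z[k, n] = rn * (np.cos(pn) + 1j * np.sin(pn))
    return z, r, psi


@njit(cache=True, fastmath=True)
def integrate_delayed(z_hist, r0, psi0, A, d_steps, G, L, delta, om_rad, dt, n_steps, r_floor):
    """Delayed-Euler integration of the reduced order-parameter equations.

    ``z_hist`` holds the complex order parameters on the delay grid with the
    last row equal to the state at t = 0 (i.e. ``r0 * exp(1j*psi0)``).
    Returns (r, psi, err_step): trajectories of shape (n_steps+1, E) and the
    step index at which a non-finite state appeared (-1 if none).
    """
    depth, E = z_hist.shape
    z = np.empty((depth + n_steps, E), np.complex128)
    z[:depth] = z_hist
    r = np.empty((n_steps + 1, E))
    psi = np.empty((n_steps + 1, E))
    rc = r0.copy()
    pc = psi0.copy()
    r[0] = rc
    psi[0] = pc
    gfac = G / (2.0 * E)
    for k in range(n_steps):
        base = depth - 1 + k
        for n in range(E):
            # delayed coupling field S_n = sum_p A_np z_p(t - tau_np)
            sre = 0.0
            sim = 0.0
            for p in range(E):
                a = A[n, p]
                if p != n and a != 0.0:
                    zz = z[base - d_steps[n, p], p]
                    sre += a * zz.real
                    sim += a * zz.imag
            rn = rc[n]
            # rotate S_n by e^{-i psi_n} using the stored unit phasor z_n / r_n
            zn = z[base, n]
            cre = (sre * zn.real + sim * zn.imag) / rn
            cim = (sim * zn.real - sre * zn.imag) / rn
            om2 = 1.0 - rn * rn
            dr = -delta * rn + 0.5 * L[n] * om2 * rn + gfac * om2 * cre
            dpsi = om_rad + gfac * (rn + 1.0 / rn) * cim
            rn2 = rn + dt * dr
            if rn2 < r_floor:
                rn2 = r_floor
            elif rn2 > 1.0:
                rn2 = 1.0
            pn2 = pc[n] + dt * dpsi
            if not (np.isfinite(rn2) and np.isfinite(pn2)):
                return r, psi, k
            pn2 = (pn2 + np.pi) % TWO_PI - np.pi
            rc[n] = rn2
            pc[n] = pn2
            z[base + 1, n] = rn2 * (np.cos(pn2) + 1j * np.sin(pn2))
            r[k + 1, n] = rn2
            psi[k + 1, n] = pn2
    return r, psi, -1


@njit(cache=True, fastmath=True)
def micro_integrate(theta0, omega, A, d_steps, G, L, dt, n_steps, depth):
    """Euler integration of the finite-N network-of-networks of phase oscillators.

    ``theta0``/``omega`` have shape (E, N).  The first ``depth - 1`` steps
    evolve each ensemble decoupled (history fill, matching the reduced
    model's initialization); coupled integration then runs for ``n_steps``.
    Returns the per-ensemble complex Kuramoto order parameter ``z`` sampled
    at every step, shape (depth + n_steps, E), with row ``depth - 1`` at
    t = 0, together with the final oscillator phases (E, N).
    """
    E, N = theta0.shape
    total = depth + n_steps
    z = np.empty((total, E), np.complex128)
    theta = theta0.copy()
    ct = np.empty((E, N))
    st = np.empty((E, N))
    for n in range(E):
        zr = 0.0
        zi = 0.0
        for i in range(N):
            c = np.cos(theta[n, i])
            s = np.sin(theta[n, i])
            ct[n, i] = c
            st[n, i] = s
            zr += c
            zi += s
        z[0, n] = complex(zr / N, zi / N)
    gfac = G / E
    for k in range(1, total):
        base = k - 1
        coupled = base >= depth - 1
        for n in range(E):
            # local mean field plus (once past the history fill) delayed input
            are = L[n] * z[base, n].real
            aim = L[n] * z[base, n].imag
            if coupled:
                for p in range(E):
                    a = A[n, p]
                    if p != n and a != 0.0:
                        zz = z[base - d_steps[n, p], p]
                        are += gfac * a * zz.real
                        aim += gfac * a * zz.imag
            zr = 0.0
            zi = 0.0
            for i in range(N):
                th = theta[n, i] + dt * (omega[n, i] + aim * ct[n, i] - are * st[n, i])
                theta[n, i] = th
                c = np.cos(th)
                s = np.sin(th)
                ct[n, i] = c
                st[n, i] = s
                zr += c
                zi += s
            z[k, n] = complex(zr / N, zi / N)
    return z, theta
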