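"""Shared oracle helpers used by more than one test module."""

import numpy as np

from poroperf import column1d as C


def two_compartment_cosh_mismatch(k=2.0, beta=0.5, L=3.0, cpp=10.0):
    """Worst-case mismatch between the modal solver and the closed-form
    two-compartment solution.

    For equal permeabilities, a single coupling and antisymmetric Dirichlet
    data (+cpp/-cpp) with a sealed far end, the pressure difference obeys
    d'' = (2 beta / k) d, so d = 2 cpp cosh(a (L - x)) / cosh(a L) with
    a = sqrt(2 beta / k) — an independent closed form.
    """
    bcs = [C.ColumnBC(0, 0, "dirichlet", cpp),
           C.ColumnBC(1, 0, "dirichlet", -cpp),
           C.ColumnBC(0, 1, "neumann", 0.0),
           C.ColumnBC(1, 1, "neumann", 0.0)]
    bmat = np.array([[0.0, beta], [beta, 0.0]])
    prob = C.ColumnProblem(k=np.array([k, k]), subdomains=[(L, bmat)], bcs=bcs)
    sol = C.solve_column(prob)
    a = np.sqrt(2 * beta / k)
    x = np.linspace(0.0, L, 201)
    p = sol.pressure(x)
    exact = 2 * cpp * np.cosh(a * (L - x)) / np.cosh(a * L)
    return float(np.abs((p[0] - p[1]) - exact).max() / cpp)
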