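"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: clustering by
transitive closure over the full pairwise distance matrix, and transport
by explicit small-step Euler integration of the stopping power.
"""

import numpy as np

from radonmc.nanotrack import CLUSTER_EPS_NM


def brute_force_clusters(positions, strands, eps=CLUSTER_EPS_NM):
    """Transitive-closure clustering; returns (n_dsb, n_complex)."""
    n = len(strands)
    if n < 2:
        return 0, 0
    pos = np.asarray(positions, dtype=float)
    d2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=-1)
    adj = (d2 <= eps ** 2)
    np.fill_diagonal(adj, False)
    # union-find
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if adj[i, j]:
                ra, rb = find(i), find(j)
                if ra != rb:
                    parent[ra] = rb
    roots = np.array([find(i) for i in range(n)])
    n_dsb = n_complex = 0
    for r in np.unique(roots):
        members = roots == r
        if members.sum() < 2:
            continue
        s = np.asarray(strands)[members]
        if (s == 1).any() and (s == 2).any():
            n_dsb += 1
            if members.sum() > 2:
                n_complex += 1
    return n_dsb, n_complex


def euler_energy_after(table, e0_mev, path_um, density=1.0, ds_um=1e-3):
    """Explicit-step CSDA slowing: dE = S(E) * ds until path is exhausted."""
    e = float(e0_mev)
    floor = table.energies[0]
    s = 0.0
    while s < path_um:
        if e <= floor:
            return 0.0
        step = min(ds_um, path_um - s)
        e -= float(table.let(e)) * density * step * 1e-3
        s += step
    return max(e, 0.0)


def trapezoid_range(table, e0_mev, n_points=40000):
    """CSDA range by trapezoidal quadrature on a 10x finer energy grid."""
    e = np.geomspace(table.energies[0], e0_mev, n_points)
    inv = 1.0 / table.let(e)
    return float(np.trapezoid(inv, e) * 1e3)


def stepwise_integrate_hit(library, e_entry, chord_um, p_f, step_um=1e-3):
    """Explicit per-step chord integration with library mean rates."""
    e = float(e_entry)
    s = 0.0
    dsb = cplx = 0.0
    edep = 0.0
    while s < chord_um and e > library.floor:
        step = min(step_um, chord_um - s)
        r_e, r_d, r_c = library.rates_per_um(e)
        de_kev = float(r_e) * step
        dsb += float(r_d) * step * p_f
        cplx += float(r_c) * step * p_f
        edep += de_kev
        e -= de_kev * 1e-3
        s += step
    if e <= library.floor:
        edep += e * 1e3
        e = 0.0
    return edep, dsb, cplx
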