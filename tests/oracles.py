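"""Independent brute-force oracles used to cross-check the implementation.

The exhaustive enumerator below shares no code with the package's
vectorized formula search: it loops over the full integer ranges of every
element (including the complete hydrogen range compatible with the mass
window) in plain Python.
"""

import math

MC, MH, MO = 12.0, 1.00782503, 15.99491462
MN, MS, MP = 14.00307401, 31.97207069, 30.97376151


def exhaustive_enumerate(
    target_mass,
    tol_ppm,
    c_max=100,
    h_max=250,
    o_min=1,
    o_max=100,
    n_max=4,
    s_max=2,
    p_max=1,
):
    """Every CHNOSP formula within tol_ppm of target_mass, as count tuples.

    Applies the same chemical filters as the pipeline (H <= 2C+2+N,
    integer DBE >= 0) but discovers candidates by scanning the complete
    hydrogen range for every skeleton.
    """
    tol = tol_ppm * 1e-6 * target_mass
    hi = target_mass + tol
    found = []
    for c in range(1, min(c_max, int(hi // MC)) + 1):
        mass_c = c * MC
        if mass_c + MH > hi:
            break
        for o in range(o_min, o_max + 1):
            mass_co = mass_c + o * MO
            if mass_co + MH > hi:
                break
            for n in range(0, n_max + 1):
                for s in range(0, s_max + 1):
                    for p in range(0, p_max + 1):
                        skel = mass_co + n * MN + s * MS + p * MP
                        h_lo = max(1, math.ceil((target_mass - tol - skel) / MH))
                        h_hi = min(h_max, math.floor((target_mass + tol - skel) / MH))
                        for h in range(h_lo, h_hi + 1):
                            if abs(skel + h * MH - target_mass) > tol:
                                continue
                            if h > 2 * c + 2 + n:
                                continue
                            if (h % 2) != ((n + p) % 2):
                                continue
                            if 2 + 2 * c - h + n + p < 0:
                                continue
                            found.append((c, h, o, n, s, p))
    return found
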