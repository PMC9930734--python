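"""Independent straight-line re-evaluation of the energy equations.

Written as plain scalar arithmetic, separately from the package's
vectorized implementation, to serve as an oracle: every function here is a
direct transcription of the published net-energy forms with no shared code
with ``cowcalfsim.nutrition``.
"""

import math


def oracle_lactation(pl, age_years, n_weeks, k=0.1175):
    if age_years <= 2:
        af = 0.74
    elif age_years == 3:
        af = 0.88
    else:
        af = 1.0
    a = 1.0 / (pl * k * math.e)
    return (n_weeks / a) * math.exp(-k * n_weeks) * af


def oracle_nemr(csbw, temp_c, nemlg, factor=1.0):
    return ((0.0007 * (20.0 - temp_c) + 0.077) * csbw**0.75 + nemlg) * factor


def oracle_nepreg(cbw, t):
    return cbw * (0.05855 - 0.0000996 * t) * math.exp(0.03233 * t - 0.0000275 * t * t) / 1000.0


def oracle_mepreg(cbw, t):
    return oracle_nepreg(cbw, t) / 0.13


def oracle_nemg(cbw, t):
    return 0.576 * oracle_mepreg(cbw, t)


def oracle_dmi_cow(csbw, nemd, lact, t):
    coef = 0.0384 if t <= 93 else 0.04631
    nema = nemd if nemd >= 1.0 else 0.95
    return csbw**0.75 * (coef + 0.04997 * nemd**2) / nema + 0.2 * lact


def oracle_dmi_pct_young(nemd):
    return (1.2425 + 1.9218 * nemd - 0.7259 * nemd**2) / 100.0


def oracle_sbg_young(csbw, mw, negi, ebl):
    eqsbw = (478.0 / mw) * csbw
    ebw = 0.891 * eqsbw
    return 12.341 * ebw**-0.6837 * negi**0.9116 + ebl / 0.956


def oracle_ebl(nemi, nemr, mcal_per_kg):
    if nemi < nemr:
        return (nemi - nemr) / mcal_per_kg
    return 0.0


def oracle_bfg(negi, ebl, nemi, nemr):
    if nemi > nemr:
        return max(0.15 * negi - 0.0057 * negi**2 - 0.162, 0.0)
    return ebl


def oracle_sbg_mature(nemi, nemr, mcal_gain, mcal_loss):
    if nemi < nemr:
        ebl = (nemi - nemr) / mcal_loss
        ebg = 0.0
    else:
        ebl = 0.0
        ebg = (nemi - nemr) / mcal_gain
    return (ebg + ebl) / 0.956


def oracle_negi(dmi, nemd, negd, nemr):
    return max(negd * (dmi - nemr / nemd), 0.0)


def oracle_ww_gp_base(sire_mw_kg):
    return 0.42 * 1400.0 + (sire_mw_kg * 2.205 - 1400.0) * 0.125


def oracle_bw_gp_base(ww_base_lb, ww_ebv_1992_lb):
    return 0.037 * (ww_base_lb + ww_ebv_1992_lb) + 54.202


def oracle_badg_lb(ww_gp, ww_adj, bw_gp, bw_adj):
    return ((ww_gp - ww_adj) - (bw_gp - bw_adj)) / 205.0


def oracle_max_adg(baww, weight, age, weaning_age):
    return max((baww - weight) / (weaning_age - age), 0.0)
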