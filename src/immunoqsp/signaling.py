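"""T cell intracellular signaling: hub activation, checkpoint modulation, cytokines.

The cascade is modeled at the level of five hub proteins — ZAP70 and PI3K
proximal to the TCR/CD28 inputs, then AKT (from PI3K) and ERK/NF-kB (from
ZAP70).  Each hub carries a normalized active fraction x* in [0, 1] obeying

    dx*/dt = kf * (prod upstream activities) * (prod modulation factors) * (1 - x*)
             - kr * x*

i.e. multiplicative signal transduction with unconsumed upstream modulators.
Checkpoint complexes act through saturating Hill factors: inhibitory
complexes divide the activation flux, stimulatory complexes multiply it.
LAG3 is distinct: it gates TCR initiation upstream of every hub (adaptor
sequestration from the CD4/CD8 co-receptors), rather than acting at a hub.

Adaptor proteins (SHP2, SHIP1, Lck, TRAFs) are not explicit states; their
action is absorbed into the Hill modulation strengths (the km4..km12 family,
see the regulatory link table).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

HUBS = ("ZAP70", "PI3K", "AKT", "ERK", "NFkB")

#: Fixed checkpoint-complex -> hub regulatory map with its km index.
#: (km name, driving complex key, target hub, sign, emax name or None)
REGULATORY_LINKS = (
    ("km4", "PD-1:PD-L1", "ZAP70", "inhibitory", None),
    ("km5", "PD-1:PD-L1", "PI3K", "inhibitory", None),
    ("km6", "TIGIT:CD155", "ZAP70", "inhibitory", None),
    ("km7", "TIGIT:CD155", "NFkB", "inhibitory", None),
    ("km8", "4-1BB*", "ERK", "stimulatory", "emax_41BB_ERK"),
    ("km9", "4-1BB*", "AKT", "stimulatory", "emax_41BB_AKT"),
    ("km10", "OX40*", "AKT", "stimulatory", "emax_OX40_AKT"),
    ("km11", "OX40*", "NFkB", "stimulatory", "emax_OX40_NFkB"),
    ("km12", "CTLA4:CD8086", "ZAP70", "inhibitory", None),
)
# "4-1BB*" / "OX40*" denote the engaged receptor pool: natural-ligand complex
# plus agonist-antibody-bound receptor (dimer + weighted trimer).


def checkpoint_modulation_factor(complex_level, km, h=1.0, sign="inhibitory", emax=1.0):
    """Hill-type multiplier a checkpoint complex applies to a hub's activation.

    Inhibitory: f = 1 / (1 + (C/km)^h), in (0, 1].
    Stimulatory: f = 1 + emax * C^h / (km^h + C^h), in [1, 1 + emax].
    C = 0 gives exactly 1 (no modulation) in both cases.
    """
    C = np.asarray(complex_level, dtype=float)
    if np.any(np.asarray(km) <= 0):
        raise ValueError("km must be > 0")
    r = (C / km) ** h
    if sign == "inhibitory":
        return 1.0 / (1.0 + r)
    if sign == "stimulatory":
        return 1.0 + emax * r / (1.0 + r)
    raise ValueError(f"unknown sign {sign!r}")


def hub_activation_rhs(x, kf, kr, upstream=1.0, modulation=1.0):
    """d(active fraction)/dt for one hub.

    ``upstream`` is the product of upstream activities (unconsumed),
    ``modulation`` the product of checkpoint modulation factors.  The
    (1 - x) capacity term keeps x in [0, 1] for any non-negative inputs.
    """
    return kf * upstream * modulation * (1.0 - x) - kr * x


def hub_steady_state(kf, kr, stimulus=1.0, modulation=1.0):
    """Analytic fixed point kf*S / (kf*S + kr) of the hub equation."""
    drive = kf * stimulus * modulation
    return drive / (drive + kr)


def lag3_tcr_gate(lag3_complex, km_lag3, h=1.0):
    """Gate factor on TCR initiation from engaged LAG3.

    Multiplies the TCR input upstream of every hub by 1/(1 + (C/km)^h),
    which distinguishes LAG3 (signal-initiation block) from the hub-level
    checkpoint links.
    """
    C = np.asarray(lag3_complex, dtype=float)
    if np.any(np.asarray(km_lag3) <= 0):
        raise ValueError("km_lag3 must be > 0")
    return 1.0 / (1.0 + (C / km_lag3) ** h)


def cytokine_drive(nfkb, erk, akt):
    """Normalized multiplicative drive g in [0, 1] for cytokine production."""
    return nfkb * erk * akt


def cytokine_rhs(conc, kf_cyt, kdeg, drive):
    """dC/dt = kf_cyt * g - kdeg * C; zero drive decays to zero."""
    return kf_cyt * drive - kdeg * conc


def ctla4_induction_rhs(ct_per_cell, activation, basal, ceiling, k_induction):
    """Activation-induced surface CTLA4 (copies/cell).

    Relaxes first-order toward an activation-dependent target between the
    basal level and the ceiling; for constant activation the time course is
    the closed-form exponential ct(t) = target + (ct0 - target) e^(-k t).
    Every other checkpoint total is constant.
    """
    target = basal + (ceiling - basal) * np.clip(activation, 0.0, 1.0)
    return k_induction * (target - ct_per_cell)


def tcr_desensitization_rhs(resource, occupancy, kdes, krec):
    """Responsive TCR fraction R: engagement drives desensitization.

    dR/dt = krec (1 - R) - kdes * occupancy * R.  The effective TCR input is
    occupancy * R, which under a sustained stimulus rises then falls — the
    transient phospho-protein shape seen in stimulation assays.
    """
    return krec * (1.0 - resource) - kdes * occupancy * resource
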