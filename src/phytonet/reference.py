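"""Published module-metabolite correlation records.

The nine reported correlations between inositol-phosphate abundances
(IP1-IP6) and co-expression module eigengenes in the maize embryo study
this pipeline re-implements. They serve as a worked input for the module
selection rule (|r| > 0.8 and p < 0.01 yields six distinct modules).
"""

from __future__ import annotations

from .coexpression import ModuleTraitRecord

#: (metabolite, module, r, p) as printed
IP_MODULE_CORRELATIONS = [
    ("IP1", "dodgerblue4", 0.87, 3e-4),
    ("IP2", "salmon1", -0.98, 4e-4),
    ("IP2", "burlywood2", 0.96, 3e-4),
    ("IP3", "burlywood2", 0.86, 3e-4),
    ("IP4", "magenta2", -0.87, 2e-3),
    ("IP5", "cornsilk", 0.91, 1e-4),
    ("IP6", "steelblue4", 0.81, 2e-4),
    ("IP6", "cornsilk", 0.86, 3e-4),
    ("IP6", "magenta2", -0.87, 3e-4),
]

#: guide genes anchoring the candidate screen (maize gene ids)
GUIDE_GENES = {
    "GRMZM2G361593": "MIK",
    "GRMZM2G456626": "ITPK",
    "GRMZM2G155242": "MIPS",
    "GRMZM5G820122": "ABC-transporter",
}


def ip_module_records(r_min: float = 0.8, p_max: float = 0.01) -> list[ModuleTraitRecord]:
    """The printed records as ModuleTraitRecord objects with the selection
    flag evaluated at the given thresholds."""
    return [
        ModuleTraitRecord(module=mod, metabolite=met, r=r, p=p,
                          selected=bool(abs(r) > r_min and p < p_max))
        for met, mod, r, p in IP_MODULE_CORRELATIONS
    ]
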