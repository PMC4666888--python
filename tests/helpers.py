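"""Shared construction helpers for degenerate model configurations."""

import dataclasses

import numpy as np

from odxcea.mortality import LifeTable


def degenerate_params(params, r=0.0):
    """No recurrence, no chemotherapy, optional discounting."""
    zero_groups = {g: 0.0 for g in params.risks.p10_no_chemo}
    zero_ao = {a: 0.0 for a in params.risks.marginal_no_chemo}
    risks = dataclasses.replace(
        params.risks,
        p10_no_chemo=dict(zero_groups),
        p10_chemo=dict(zero_groups),
        marginal_no_chemo=dict(zero_ao),
        marginal_chemo=dict(zero_ao),
    )
    pattern = dataclasses.replace(
        params.pattern,
        by_group_t1={g: 0.0 for g in params.pattern.by_group_t1},
        by_group_t2={g: 0.0 for g in params.pattern.by_group_t2},
        by_ao={a: 0.0 for a in params.pattern.by_ao},
    )
    econ = dataclasses.replace(params.econ, discount_rate=r)
    return dataclasses.replace(params, risks=risks, pattern=pattern, econ=econ)


def forced_survival_table(start=50, years=50):
    """Certain survival from `start` until the terminal age."""
    qx = np.zeros(years)
    qx[-1] = 1.0
    return LifeTable(start_age=start, qx=qx)


def constant_mortality_table(mu, start=50, years=400):
    import math

    qx = np.full(years, 1 - math.exp(-mu))
    qx[-1] = 1.0
    return LifeTable(start_age=start, qx=qx)
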