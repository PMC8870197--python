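"""Independent straight-line transcription of the network's phase equations.

Deliberately written with explicit Python loops and ``math.exp``, term by
term, so it shares no code path with the vectorized implementation it
cross-checks.
"""

import math


def phase_oracle(
    weights,
    params,
    y_in,
    snc_levels,
    pfc_stimulus=None,
    y_pfc=0,
    chosen_override=None,
):
    """Evaluate one phase of the network unit by unit.

    ``snc_levels`` is the per-striatal-unit SNc output (length 2N), built by
    the caller.  Returns a dict of every layer's activities plus the choice.
    """
    n = weights.n_stimuli
    a = params.a

    def f(x):
        return math.exp(-a * (1.0 - x) ** 2)

    y_stria = []
    for k in range(2 * n):
        pre = weights.w_snc_stria[k] * snc_levels[k]
        for i in range(n):
            pre += weights.w_in_stria[i, k] * y_in[i]
        if y_pfc and pfc_stimulus is not None and k == pfc_stimulus:
            pre += params.w_pfc_stria
        y_stria.append(f(pre))

    y_gpe = [1.0 - y_stria[n + k] for k in range(n)]
    y_gpi = [max(1.0 - 0.5 * y_stria[k] - 0.5 * y_gpe[k], 0.0) for k in range(n)]
    y_thal = [1.0 - y_gpi[k] for k in range(n)]

    x_pmc = []
    for k in range(n):
        s = 0.0
        for i in range(n):
            s += weights.w_in_pmc[i, k] * y_in[i]
        x = 0.5 * y_thal[k] + 0.5 * s
        if y_pfc and pfc_stimulus is not None and k == pfc_stimulus:
            x += params.w_pfc_pmc
        x_pmc.append(x)
    m = max(x_pmc)
    if m > 1.0:
        x_pmc = [x / m for x in x_pmc]
    y_pmc = [f(x) for x in x_pmc]

    if chosen_override is None:
        presented = [i for i in range(n) if y_in[i] == 1]
        chosen = presented[0]
        for i in presented[1:]:
            if y_pmc[i] > y_pmc[chosen]:
                chosen = i
    else:
        chosen = chosen_override

    return {
        "y_stria": y_stria,
        "y_gpe": y_gpe,
        "y_gpi": y_gpi,
        "y_thal": y_thal,
        "x_pmc": x_pmc,
        "y_pmc": y_pmc,
        "chosen": chosen,
    }
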