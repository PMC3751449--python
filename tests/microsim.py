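"""Individual-level Monte Carlo simulator used as an independent oracle.

Re-implements the cohort model's per-cycle probabilities as person-level
random draws (death, quitting, relapse, mutually exclusive disease events)
using only the public rate-derivation API, so that agreement with the
deterministic cohort engine validates the engine's expectation arithmetic.
"""

import numpy as np

import quitcea as qc

SMOKER, FR, FL, DEAD = 0, 1, 2, 3


def simulate_people(inputs, arm, start_age, gender, n_persons, seed):
    """Simulate ``n_persons`` individuals; returns per-person discounted
    (cost, ly, qaly) arrays."""
    rates = qc.derive_status_rates(inputs.epi)
    sub = rates.cycle.xs(gender, level="gender").sort_index()
    age0 = int(sub.index.min())
    m_s = sub["m_smoker"].to_numpy()
    m_f = sub["m_former"].to_numpy()
    q_s = sub[[f"q_smoker_{d}" for d in inputs.diseases]].to_numpy()
    q_f = sub[[f"q_former_{d}" for d in inputs.diseases]].to_numpy()

    nd = len(inputs.diseases)
    cost_vec = np.array(
        [inputs.costs.disease_annual_cost[d] for d in inputs.diseases] + [0.0]
    )
    u_disease = [inputs.utilities.disease_value[d] for d in inputs.diseases]
    u_smoker = np.array(u_disease + [inputs.utilities.smoker_value])
    u_former = np.array(u_disease + [inputs.utilities.former_value])

    quit = inputs.quit
    econ = inputs.econ
    half = econ.cycle_length
    n_cycles = int(round((econ.horizon_age - start_age) / half))
    p21 = quit.relapse_6_12
    p_back = p21 + (1.0 - p21) * quit.relapse_lifetime  # combined return-to-smoking
    bgq = qc.annual_to_cycle(quit.background_quit_annual)

    rng = np.random.default_rng(seed)
    state = np.full(n_persons, SMOKER, dtype=np.int8)
    cost0 = 0.0
    if arm is qc.Arm.INTERVENTION:
        cost0 = (
            inputs.costs.intervention_cost_per_smoker
            + inputs.costs.royalty_management_per_smoker
        )
    cost = np.full(n_persons, cost0)
    ly = np.zeros(n_persons)
    qaly = np.zeros(n_persons)
    disc_c = disc_e = 1.0

    for t in range(1, n_cycles + 1):
        ia = (start_age - age0) + (t - 1) // 2
        alive = state != DEAD
        smoker = state == SMOKER
        former = alive & ~smoker
        # disease draw, mutually exclusive within the cycle ("none" = index nd)
        u = rng.random(n_persons)
        event = np.full(n_persons, nd)
        event[smoker] = np.searchsorted(np.cumsum(q_s[ia]), u[smoker], side="right")
        event[former] = np.searchsorted(np.cumsum(q_f[ia]), u[former], side="right")
        ly[alive] += half * disc_e
        qaly[smoker] += half * disc_e * u_smoker[event[smoker]]
        qaly[former] += half * disc_e * u_former[event[former]]
        cost[alive] += half * disc_c * cost_vec[event[alive]]
        disc_c *= (1.0 + econ.discount_rate_cost) ** (-half)
        disc_e *= (1.0 + econ.discount_rate_effect) ** (-half)
        # transitions: death -> quit -> relapse
        u2 = rng.random(n_persons)
        dies = (smoker & (u2 < m_s[ia])) | (former & (u2 < m_f[ia]))
        state[dies] = DEAD
        qp = qc.quit_prob_schedule(arm, t, quit)
        u3 = rng.random(n_persons)
        quits = (state == SMOKER) & (u3 < qp)
        was_fr = state == FR
        u4 = rng.random(n_persons)
        state[was_fr & (u4 < p_back)] = SMOKER
        state[was_fr & (u4 >= p_back)] = FL
        state[quits] = FR
    return cost, ly, qaly
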