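"""Independent straight-line transcription of the coupled update equations.

Deliberately written with plain Python loops and no shared code with the
package's step implementation, so it can serve as a brute-force oracle:
per-type values by linear interpolation, utility sums, capacities with the
plant cap, the logistic update, uniform-relaxation variation, and the
replicator reweighting — composed in the same synchronous order.
"""

from __future__ import annotations


def oracle_step(state, params):
    """One step of the dynamics, returning plain Python lists/floats."""
    H = state.humans
    P = state.plants
    pop_h = [float(x) for x in state.type_proportions_humans]
    pop_p = [float(x) for x in state.type_proportions_plants]
    n_h = params.number_types_humans
    n_p = params.number_types_plants

    def interp(v1, vn, n, i):  # i is 1-based
        return v1 + (i - 1) * (vn - v1) / (n - 1)

    # per-type utilities
    u_hip = [
        interp(
            params.utility_per_capita_type_1_humans_to_plants,
            params.utility_per_capita_type_n_humans_to_plants,
            n_h, i,
        )
        for i in range(1, n_h + 1)
    ]
    u_pih = [
        interp(
            params.utility_per_capita_type_1_plants_to_humans,
            params.utility_per_capita_type_n_plants_to_humans,
            n_p, i,
        )
        for i in range(1, n_p + 1)
    ]
    u_bhi = [
        interp(
            params.utility_other_to_type_1_humans,
            params.utility_other_to_type_n_humans,
            n_h, i,
        )
        for i in range(1, n_h + 1)
    ]
    u_bpi = [
        interp(
            params.utility_other_to_type_1_plants,
            params.utility_other_to_type_n_plants,
            n_p, i,
        )
        for i in range(1, n_p + 1)
    ]

    # aggregate utilities and baselines
    u_hp = H * sum(pop_h[i] * u_hip[i] for i in range(n_h))
    u_ph = P * sum(pop_p[i] * u_pih[i] for i in range(n_p))
    u_bh = sum(pop_h[i] * u_bhi[i] for i in range(n_h))
    u_bp = sum(pop_p[i] * u_bpi[i] for i in range(n_p))

    # carrying capacities (plant one capped)
    k_h = u_ph + u_bh
    k_p = min(u_hp + u_bp, params.max_area)

    # logistic population updates
    def logistic(pop, r, k):
        # populations are defined as nonnegative; the update never goes below 0
        if k == 0.0:
            return max(pop * (1.0 - r), 0.0)
        return max(pop + r * pop - r * pop * pop / k, 0.0)

    new_h = logistic(H, params.intrinsic_growth_rate_humans, k_h)
    new_p = logistic(P, params.intrinsic_growth_rate_plants, k_p)

    # fitness scores
    def fitness(n, ub, uo):
        if ub + uo == 0.0:
            return [1.0] * n
        return [((n - i) * ub + i * uo) / (ub + uo) for i in range(1, n + 1)]

    fit_h = fitness(n_h, u_bh, u_ph)
    fit_p = fitness(n_p, u_bp, u_hp)

    # undirected variation then replicator
    def evolve(pop, v, fit):
        n = len(pop)
        varied = [pop[i] + v * (1.0 / n - pop[i]) for i in range(n)]
        total = sum(fit[i] * varied[i] for i in range(n))
        if total == 0.0:
            return varied
        return [fit[i] * varied[i] / total for i in range(n)]

    new_pop_h = evolve(pop_h, params.undirected_variation_humans, fit_h)
    new_pop_p = evolve(pop_p, params.undirected_variation_plants, fit_p)

    return {
        "humans": new_h,
        "plants": new_p,
        "pop_humans": new_pop_h,
        "pop_plants": new_pop_p,
        "U_HP": u_hp,
        "U_PH": u_ph,
        "U_bH": u_bh,
        "U_bP": u_bp,
        "K_H": k_h,
        "K_P": k_p,
        "fitness_humans": fit_h,
        "fitness_plants": fit_p,
    }
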