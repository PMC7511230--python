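"""Independent stochastic oracles used by the tests: small discrete-event
simulations of the MT-CFG kinetics that share no code with the analytic
implementation they check."""

import numpy as np


def gillespie_occupancy(omegas, kappa, t_end, rng):
    """Continuous-time Markov chain of one CFG site shared by n
    centrosomes: state 0 = empty, state i = bound to an MT from
    centrosome i.  Returns the fraction of time spent bound to each
    centrosome."""
    omegas = np.asarray(omegas, dtype=float)
    n = len(omegas)
    occ = np.zeros(n)
    state = 0  # empty
    t = 0.0
    while t < t_end:
        if state == 0:
            total = omegas.sum()
            if total <= 0:
                break
            dt = rng.exponential(1.0 / total)
            t_next = min(t + dt, t_end)
            if t + dt <= t_end:
                state = 1 + rng.choice(n, p=omegas / total)
            t = t_next
        else:
            dt = rng.exponential(1.0 / kappa)
            t_next = min(t + dt, t_end)
            occ[state - 1] += t_next - t
            if t + dt <= t_end:
                state = 0
            t = t_next
    return occ / t_end


def gillespie_occupancy_se(omegas, kappa, t_end, rng, n_chains=8):
    """Mean and standard error of occupancies over independent chains."""
    runs = np.array([
        gillespie_occupancy(omegas, kappa, t_end, rng) for _ in range(n_chains)
    ])
    return runs.mean(axis=0), runs.std(axis=0, ddof=1) / np.sqrt(n_chains)


def discrete_event_impingement_rate(d, params, t_end, rng):
    """Event-driven estimate of the rate MTs impinge on a face-on disk of
    radius r at distance d: sample nucleation events (Poisson, rate
    gamma), isotropic directions, and exponential catastrophe lengths;
    count MTs whose direction lies in the capture cone and that survive
    to length d."""
    g = params.nucleation_rate
    n_events = rng.poisson(g * t_end)
    # isotropic direction: cos(theta) uniform on [-1, 1]
    cos_theta = rng.uniform(-1.0, 1.0, size=n_events)
    cos_cone = d / np.hypot(d, params.capture_radius)
    in_cone = cos_theta > cos_cone
    length = rng.exponential(
        params.growth_speed / params.catastrophe_rate, size=in_cone.sum())
    hits = np.count_nonzero(length >= d)
    rate = hits / t_end
    se = np.sqrt(max(hits, 1)) / t_end
    return rate, se


def birth_death_time_average(birth_rate, death_rate_per, t_end, burn_in, rng):
    """Time-averaged population of a linear birth-death process
    (constant birth, per-capita death), plus a standard error from the
    autocorrelation time 1/death_rate_per."""
    n = 0
    t = 0.0
    acc = 0.0
    acc_t = 0.0
    while t < t_end:
        total = birth_rate + death_rate_per * n
        dt = rng.exponential(1.0 / total)
        t_next = min(t + dt, t_end)
        if t_next > burn_in:
            lo = max(t, burn_in)
            acc += n * (t_next - lo)
            acc_t += t_next - lo
        if t + dt <= t_end:
            if rng.uniform() < birth_rate / total:
                n += 1
            else:
                n -= 1
        t = t_next
    mean = acc / acc_t
    tau = 1.0 / death_rate_per
    var = birth_rate / death_rate_per  # Poisson stationary variance
    se = np.sqrt(var * 2.0 * tau / acc_t)
    return mean, se
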