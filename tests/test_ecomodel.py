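"""Unit tests of the simulator's process kernels and single Euler step."""

import math

import numpy as np
import pytest

from minibloom import ecomodel as em
from minibloom.ecomodel import (
    GRAMS_C_PER_MOL,
    QUOTA_RELAX_RATE,
    BacteriaParams,
    CommunityState,
    ExperimentSpec,
    ForcingConfig,
    StrategistTraits,
    TraitsTable,
)


def make_traits(**over):
    base = dict(
        name="C1", strategy="C1", uses_silicon=False,
        mu_max=1.0, alpha_chl=1.0, theta_max=0.05,
        K_NO3=1.0, K_PO4=0.05, K_DOM=1.0,
        Qmin_N=0.05, Qmax_N=0.15, Qmin_P=0.003, Qmax_P=0.009,
        m=0.1, exud_frac=0.05,
    )
    base.update(over)
    return StrategistTraits(**base)


def single_state(traits, C=1.0, qn=None, qp=None, theta=None, **env):
    qn = 0.5 * (traits.Qmin_N + traits.Qmax_N) if qn is None else qn
    qp = 0.5 * (traits.Qmin_P + traits.Qmax_P) if qp is None else qp
    theta = 0.5 * traits.theta_max if theta is None else theta
    defaults = dict(BC=0.0, BN=0.0, BP=0.0, NO3=0.0, PO4=0.0, SiOH4=0.0,
                    DOC=0.0, DON=0.0, DOP=0.0, dBSi=0.0, time=0.0)
    defaults.update(env)
    return CommunityState(
        C=np.array([C]), N=np.array([qn * C]), P=np.array([qp * C]),
        Si=np.array([0.0]), Chl=np.array([theta * C * GRAMS_C_PER_MOL]),
        **defaults,
    )


# ---------------------------------------------------------------------------
# forcing and saturation kernels
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "t, forcing_kwargs, expected",
    [
        (0.25, {}, 300.0),                       # 06:00, light phase
        (0.75, {}, 0.0),                         # 18:00, dark phase
        (3.9, {"photoperiod_h": 24}, 300.0),     # continuous light
        (1.25, {}, 300.0),                       # periodicity
        (0.0, {"photoperiod_h": 0}, 0.0),        # permanent dark
    ],
)
def test_light_field_square_wave(t, forcing_kwargs, expected):
    assert em.light_field(t, ForcingConfig(**forcing_kwargs)) == expected


def test_light_field_rejects_negative_time():
    with pytest.raises(ValueError):
        em.light_field(-0.1, ForcingConfig())


@pytest.mark.parametrize(
    "S, K, expected",
    [(2.0, 2.0, 0.5), (0.0, 1.5, 0.0), (8.40, 1.0, 8.4 / 9.4)],
)
def test_mm_limitation(S, K, expected):
    assert em.mm_limitation(S, K) == pytest.approx(expected, rel=1e-12)


def test_mm_limitation_rejects_nonpositive_K():
    with pytest.raises(ValueError):
        em.mm_limitation(1.0, 0.0)


def test_quota_status_droop_and_headroom():
    tr = make_traits(Qmin_N=0.05, Qmax_N=0.15)
    q, droop, head = em.quota_status(0.10 * 2.0, 2.0, tr, "N")
    assert q == pytest.approx(0.10)
    assert droop == pytest.approx(0.5)
    assert head == pytest.approx(0.5)
    # starvation shuts growth, repletion shuts uptake
    assert em.quota_status(0.05, 1.0, tr, "N")[1] == 0.0
    assert em.quota_status(0.15, 1.0, tr, "N")[2] == 0.0


def test_quota_status_empty_pool_signals():
    with pytest.raises(ValueError):
        em.quota_status(0.1, 0.0, make_traits(), "N")


def test_gross_photosynthesis_limits_and_closed_form():
    tr = make_traits(alpha_chl=1.0)
    # dark
    assert em.gross_photosynthesis(tr, 1.0, 1.0, 0.0, 1.0) == 0.0
    # saturating light approaches the nutrient-set cap
    chl = 1.0 * GRAMS_C_PER_MOL          # theta = 1 g:g
    sat = em.gross_photosynthesis(tr, 1.0, chl, 1e6, 1.0)
    assert sat == pytest.approx(1.0, rel=1e-9)
    # alpha*theta*E = growth_cap = 1 -> 1 - 1/e
    mid = em.gross_photosynthesis(tr, 1.0, chl, 1.0, 1.0)
    assert mid == pytest.approx(1.0 - math.exp(-1.0), rel=1e-12)


def test_chl_synthesis_regulation():
    tr = make_traits(theta_max=0.05, alpha_chl=2.0)
    # when light capture exactly balances fixation, allocation is theta_max
    theta, E = 0.025, 10.0
    pc = tr.alpha_chl * theta * E
    out = em.chl_synthesis(tr, pc, E, theta, C_s=2.0)
    assert out == pytest.approx(tr.theta_max * pc * GRAMS_C_PER_MOL * 2.0, rel=1e-12)
    # dark: allocation defaults to theta_max but production follows P^C = 0
    assert em.chl_synthesis(tr, 0.0, 0.0, theta) == 0.0
    # saturating light down-regulates allocation below theta_max
    pc_sat = 0.9
    x = tr.alpha_chl * theta * 1e4
    rho = em.chl_synthesis(tr, pc_sat, 1e4, theta) / (pc_sat * GRAMS_C_PER_MOL)
    assert rho == pytest.approx(tr.theta_max * pc_sat / x, rel=1e-12)
    assert rho < tr.theta_max


# ---------------------------------------------------------------------------
# uptake, exudation, mortality, recycling
# ---------------------------------------------------------------------------


def test_uptake_sufficiency_closure():
    # Vmax = mu_max * Qmax; at S = K and full headroom: V = mu*Qmax*0.5*C
    tr = make_traits(mu_max=1.0, Qmax_N=0.15, K_NO3=2.0)
    state = single_state(tr, C=10.0, qn=tr.Qmin_N, NO3=2.0)
    v_no3, *_ = em.uptake_fluxes(tr, state, 0)
    assert v_no3 == pytest.approx(1.0 * 0.15 * 0.5 * 10.0, rel=1e-12)


def test_uptake_quota_shutoff_and_zero_substrate():
    tr = make_traits()
    state = single_state(tr, C=5.0, qn=tr.Qmax_N, NO3=4.0, DON=4.0)
    v_no3, v_po4, v_si, v_don, v_dop = em.uptake_fluxes(tr, state, 0)
    assert v_no3 == 0.0 and v_don == 0.0          # headroom = 0
    assert v_si == 0.0                            # not silicified
    state2 = single_state(tr, C=5.0, qn=tr.Qmin_N, NO3=0.0)
    assert em.uptake_fluxes(tr, state2, 0)[0] == 0.0


def test_silicate_uptake_only_for_silicified():
    tr = make_traits(name="C2", strategy="C2", uses_silicon=True,
                     K_Si=1.0, Qmin_Si=0.05, Qmax_Si=0.15)
    state = single_state(tr, C=1.0, SiOH4=5.0)
    state.Si = np.array([0.06])
    assert em.uptake_fluxes(tr, state, 0)[2] > 0.0


def test_exudation_fraction_and_quota_venting():
    tr = make_traits(exud_frac=0.05)
    state = single_state(tr, C=1.0, qn=tr.Qmax_N)    # exactly at the bound
    to_doc, to_don, to_dop = em.exudation_fluxes(tr, state, 0, gross_C=2.0)
    assert to_doc == pytest.approx(0.1)
    assert to_don == 0.0                             # boundary not exceeded
    state.N = np.array([tr.Qmax_N * 1.0 + 0.02])
    assert em.exudation_fluxes(tr, state, 0, 0.0)[1] == pytest.approx(
        QUOTA_RELAX_RATE * 0.02)
    tr0 = make_traits(exud_frac=0.0)
    assert em.exudation_fluxes(tr0, single_state(tr0), 0, 5.0)[0] == 0.0


@pytest.mark.parametrize("condition, rate", [("HCC", 0.25), ("LCC", 0.10)])
def test_r_strategist_mortality_follows_control_condition(condition, rate):
    tr = make_traits(name="R", strategy="R", uses_silicon=True,
                     K_Si=1.0, Qmin_Si=0.04, Qmax_Si=0.12, m=0.05)
    state = single_state(tr, C=1.0)
    ex = ExperimentSpec(control_condition=condition)
    losses = em.mortality_fluxes(tr, state, 0, ex)
    assert losses["C"] == pytest.approx(rate * 1.0)


def test_zero_mortality_gives_zero_losses():
    tr = make_traits(m=0.0)
    losses = em.mortality_fluxes(tr, single_state(tr), 0, ExperimentSpec())
    assert all(v == 0.0 for v in losses.values())


def test_bacterial_recycling_splits_and_dissolution():
    empty = single_state(make_traits())
    assert all(v == 0.0 for v in em.bacterial_recycling(empty).values())
    params = BacteriaParams(growth_efficiency=0.3, bsi_dissolution=0.05)
    state = single_state(make_traits(), BC=1.0, DOC=1e9, dBSi=1.0)
    fx = em.bacterial_recycling(state, params)
    assert fx["to_BC"] == pytest.approx(0.3 * fx["uptake_DOC"], rel=1e-12)
    assert fx["respired"] == pytest.approx(0.7 * fx["uptake_DOC"], rel=1e-12)
    assert fx["bsi_dissolution"] == pytest.approx(0.05)


# ---------------------------------------------------------------------------
# single Euler step
# ---------------------------------------------------------------------------


def test_step_noop_on_empty_community():
    tr = TraitsTable([make_traits(m=0.3)])
    state = single_state(tr.traits[0], C=0.0, NO3=5.0, PO4=0.3, SiOH4=5.0)
    state.N[0] = state.P[0] = state.Chl[0] = 0.0
    forcing = ForcingConfig()
    out = em.step(state, tr, ExperimentSpec(), forcing)
    assert out.time == pytest.approx(forcing.dt_days)
    assert out.NO3 == state.NO3 and out.DOC == state.DOC
    assert np.all(out.C == 0.0)


def test_step_conserves_budgets_to_machine_precision(trait_sampler,
                                                     random_state_factory):
    rng = np.random.default_rng(7)
    forcing = ForcingConfig()
    ex = ExperimentSpec()
    for _ in range(10):
        traits = trait_sampler(rng)
        state = random_state_factory(rng, traits)
        out = em.step(state, traits, ex, forcing)
        for budget in ("total_N", "total_P", "total_Si"):
            before, after = getattr(state, budget)(), getattr(out, budget)()
            assert after == pytest.approx(before, rel=1e-12)


def _oracle_step(state, traits, experiment, forcing, bp):
    """Independent scalar re-implementation of one limited Euler step."""
    dt = forcing.dt / 86400.0
    hour = (state.time % 1.0) * 24.0
    E = forcing.irradiance_day if hour < forcing.photoperiod_h else 0.0
    n = len(traits)
    t = traits.traits

    def droop(q, qmin, qmax):
        q = max(q, 1e-300)
        return min(1.0, max(0.0, 1.0 - qmin / q) / (1.0 - qmin / qmax))

    def head(q, qmin, qmax):
        return min(1.0, max(0.0, (qmax - q) / (qmax - qmin)))

    pp, synth, vno3, vdon, vpo4, vdop, vsi = ([0.0] * n for _ in range(7))
    exud, ventn, ventp, ventsi = ([0.0] * n for _ in range(4))
    mc, mn, mp_, msi, mchl = ([0.0] * n for _ in range(5))
    for i in range(n):
        tr = t[i]
        C = state.C[i]
        cs = C if C > 0 else 1.0
        qn, qp = state.N[i] / cs, state.P[i] / cs
        dn = droop(qn, tr.Qmin_N, tr.Qmax_N)
        dp = droop(qp, tr.Qmin_P, tr.Qmax_P)
        dsi = droop(state.Si[i] / cs, tr.Qmin_Si, tr.Qmax_Si) if tr.uses_silicon else 1.0
        cap = tr.mu_max * min(dn, dp, dsi) if C > 0 else 0.0
        theta = state.Chl[i] / (12.0 * cs)
        x = tr.alpha_chl * theta * E
        pc = cap * -math.expm1(-x / cap) if (cap > 0 and x > 0) else 0.0
        pp[i] = pc * C
        rho = tr.theta_max * pc / x if x > 0 else tr.theta_max
        synth[i] = rho * pc * 12.0 * C if theta < tr.theta_max else 0.0
        hn, hp = head(qn, tr.Qmin_N, tr.Qmax_N), head(qp, tr.Qmin_P, tr.Qmax_P)
        vno3[i] = tr.mu_max * tr.Qmax_N * state.NO3 / (tr.K_NO3 + state.NO3) * hn * C
        vdon[i] = tr.mu_max * tr.Qmax_N * state.DON / (tr.K_DOM + state.DON) * hn * C
        vpo4[i] = tr.mu_max * tr.Qmax_P * state.PO4 / (tr.K_PO4 + state.PO4) * hp * C
        vdop[i] = tr.mu_max * tr.Qmax_P * state.DOP / (tr.K_DOM + state.DOP) * hp * C
        if tr.uses_silicon:
            hsi = head(state.Si[i] / cs, tr.Qmin_Si, tr.Qmax_Si)
            vsi[i] = (tr.mu_max * tr.Qmax_Si
                      * state.SiOH4 / (tr.K_Si + state.SiOH4) * hsi * C)
        exud[i] = tr.exud_frac * pp[i]
        ventn[i] = max(0.0, state.N[i] - tr.Qmax_N * C)
        ventp[i] = max(0.0, state.P[i] - tr.Qmax_P * C)
        if tr.uses_silicon:
            ventsi[i] = max(0.0, state.Si[i] - tr.Qmax_Si * C)
        m = experiment.r_mortality if tr.strategy == "R" else tr.m
        mc[i], mn[i], mp_[i] = m * C, m * state.N[i], m * state.P[i]
        msi[i], mchl[i] = m * state.Si[i], m * state.Chl[i]

    eps = bp.growth_efficiency
    u_doc = bp.vmax_doc * state.DOC / (bp.k_doc + state.DOC) * state.BC
    u_don = bp.vmax_don * state.DON / (bp.k_don + state.DON) * state.BC
    u_dop = bp.vmax_dop * state.DOP / (bp.k_dop + state.DOP) * state.BC
    mbc, mbn, mbp = (bp.mortality * v for v in (state.BC, state.BN, state.BP))
    diss = bp.bsi_dissolution * state.dBSi

    def lam(pool, sink):
        out = sink * dt
        return pool / out if (out > pool and out > 0) else 1.0

    l_no3, l_po4 = lam(state.NO3, sum(vno3)), lam(state.PO4, sum(vpo4))
    l_si4 = lam(state.SiOH4, sum(vsi))
    l_doc = lam(state.DOC, u_doc)
    l_don = lam(state.DON, sum(vdon) + u_don)
    l_dop = lam(state.DOP, sum(vdop) + u_dop)
    l_dbsi, l_bc, l_bn, l_bp = (lam(state.dBSi, diss), lam(state.BC, mbc),
                                lam(state.BN, mbn), lam(state.BP, mbp))
    l_c = [lam(state.C[i], exud[i] + mc[i]) for i in range(n)]
    l_n = [lam(state.N[i], mn[i] + ventn[i]) for i in range(n)]
    l_p = [lam(state.P[i], mp_[i] + ventp[i]) for i in range(n)]
    l_s = [lam(state.Si[i], msi[i] + ventsi[i]) for i in range(n)]
    l_ch = [lam(state.Chl[i], mchl[i]) for i in range(n)]

    out = state.copy()
    for i in range(n):
        out.C[i] = state.C[i] + dt * (pp[i] - l_c[i] * (exud[i] + mc[i]))
        out.N[i] = state.N[i] + dt * (l_no3 * vno3[i] + l_don * vdon[i]
                                      - l_n[i] * (mn[i] + ventn[i]))
        out.P[i] = state.P[i] + dt * (l_po4 * vpo4[i] + l_dop * vdop[i]
                                      - l_p[i] * (mp_[i] + ventp[i]))
        out.Si[i] = state.Si[i] + dt * (l_si4 * vsi[i]
                                        - l_s[i] * (msi[i] + ventsi[i]))
        out.Chl[i] = state.Chl[i] + dt * (synth[i] - l_ch[i] * mchl[i])
    out.NO3 = state.NO3 + dt * (-l_no3 * sum(vno3) + (1 - eps) * l_don * u_don)
    out.PO4 = state.PO4 + dt * (-l_po4 * sum(vpo4) + (1 - eps) * l_dop * u_dop)
    out.SiOH4 = state.SiOH4 + dt * (-l_si4 * sum(vsi) + l_dbsi * diss)
    out.DOC = state.DOC + dt * (sum(l_c[i] * (exud[i] + mc[i]) for i in range(n))
                                + l_bc * mbc - l_doc * u_doc)
    out.DON = state.DON + dt * (sum(l_n[i] * (mn[i] + ventn[i]) for i in range(n))
                                + l_bn * mbn - l_don * (sum(vdon) + u_don))
    out.DOP = state.DOP + dt * (sum(l_p[i] * (mp_[i] + ventp[i]) for i in range(n))
                                + l_bp * mbp - l_dop * (sum(vdop) + u_dop))
    out.dBSi = state.dBSi + dt * (sum(l_s[i] * (msi[i] + ventsi[i]) for i in range(n))
                                  - l_dbsi * diss)
    out.BC = state.BC + dt * (eps * l_doc * u_doc - l_bc * mbc)
    out.BN = state.BN + dt * (eps * l_don * u_don - l_bn * mbn)
    out.BP = state.BP + dt * (eps * l_dop * u_dop - l_bp * mbp)
    out.time = state.time + dt
    return out


def test_step_matches_flux_by_flux_oracle(trait_sampler, random_state_factory):
    rng = np.random.default_rng(11)
    ex = ExperimentSpec(control_condition="HCC")
    forcing = ForcingConfig()
    bp = BacteriaParams()
    for _ in range(25):
        traits = trait_sampler(rng)
        state = random_state_factory(rng, traits)
        got = em.step(state.copy(), traits, ex, forcing, bp)
        want = _oracle_step(state, traits, ex, forcing, bp)
        for attr in ("C", "N", "P", "Si", "Chl"):
            np.testing.assert_allclose(getattr(got, attr), getattr(want, attr),
                                       rtol=1e-12, atol=1e-15, err_msg=attr)
        for attr in ("BC", "BN", "BP", "NO3", "PO4", "SiOH4",
                     "DOC", "DON", "DOP", "dBSi"):
            assert getattr(got, attr) == pytest.approx(
                getattr(want, attr), rel=1e-12, abs=1e-15), attr


def test_experiment_spec_invariants():
    hc = ExperimentSpec(nutrient_condition="HCNC", control_condition="HCC")
    assert hc.initial_nutrients == (8.40, 0.39, 7.72)
    assert hc.r_mortality == 0.25
    lc = ExperimentSpec(nutrient_condition="LCNC", control_condition="LCC")
    assert lc.initial_nutrients == (2.66, 0.09, 2.10)
    assert lc.r_mortality == 0.10
    with pytest.raises(ValueError):
        ExperimentSpec(nutrient_condition="XXX")


def test_trait_validation_rejects_inverted_quotas():
    with pytest.raises(ValueError):
        make_traits(Qmin_N=0.2, Qmax_N=0.1)
    with pytest.raises(ValueError):
        make_traits(exud_frac=1.0)
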