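"""Fixed-effect estimation, phenotype adjustment, entry-mean heritability."""

import numpy as np
import pandas as pd
import pytest

from germpred import (
    adjust_phenotypes,
    entry_mean_heritability,
    fit_fixed_effects,
)
from germpred.exceptions import ValidationError


def make_pheno(trials, values, mgs=None, accessions=None, states=None,
               lodging=None, shattering=None, trait="oil"):
    n = len(values)
    return pd.DataFrame({
        "accession_id": accessions if accessions is not None else [f"a{i}" for i in range(n)],
        "trial_id": trials,
        "state": states if states is not None else ["S1"] * n,
        "maturity_group": mgs if mgs is not None else ["2"] * n,
        "trait": trait,
        "value": values,
        "lodging": lodging if lodging is not None else [np.nan] * n,
        "shattering": shattering if shattering is not None else [np.nan] * n,
    })


def test_single_cell_mu_is_mean():
    ph = make_pheno(["T1"] * 4, [1.0, 2.0, 3.0, 4.0])
    d = fit_fixed_effects(ph, "oil")
    assert d.mu == pytest.approx(2.5)
    assert d.trial_effects.abs().max() == pytest.approx(0.0)
    assert all(v == pytest.approx(0.0) for v in d.mg_effects.values())


def test_two_trial_contrast_recovered():
    rng = np.random.default_rng(3)
    base = rng.normal(0, 1, 20)
    ph = pd.concat([
        make_pheno(["T1"] * 20, base + 1.0, accessions=[f"a{i}" for i in range(20)]),
        make_pheno(["T2"] * 20, base - 1.0, accessions=[f"a{i}" for i in range(20)]),
    ], ignore_index=True)
    d = fit_fixed_effects(ph, "oil")
    assert d.trial_effects["T1"] - d.trial_effects["T2"] == pytest.approx(2.0, abs=1e-8)


def test_generator_cell_means_recovered():
    """With no genetic signal, the fitted (trial, MG) cell means track the
    generator's true fixed structure (the identified quantity: trial and
    nested-MG effects are only separable up to a parametrization)."""
    from germpred import SimulationConfig, TraitSpec, simulate_collection

    cfg = SimulationConfig(
        n_accessions=400, p_markers=200, n_trials=6, seed=11,
        traits={"oil": TraitSpec(19.0, 2.0, 0.0),
                "protein": TraitSpec(42.0, 3.0, 0.0),
                "yield": TraitSpec(2.2, 0.5, 0.0)},
    )
    coll = simulate_collection(cfg)
    d = fit_fixed_effects(coll.phenotypes, "oil")
    te = coll.truth.trial_effects["oil"]
    me = coll.truth.mg_effects["oil"]
    ph = coll.phenotypes[coll.phenotypes.trait == "oil"]
    # record-level noise sd: sqrt(gxe^2 + eps^2) in trait units (h2 = 0)
    noise_sd = 2.0 * np.sqrt(cfg.gxe_sd**2 + (1.0 - cfg.gxe_sd**2))
    zs = []
    for (t, mg) in sorted(d.cells):
        fitted = d.mu + d.trial_effects[t] + d.mg_effects[(t, mg)]
        true = 19.0 + te[t] + me[(t, int(mg))]
        n_cell = ((ph.trial_id == t) & (ph.maturity_group == mg)).sum()
        zs.append((fitted - true) / (noise_sd / np.sqrt(n_cell)))
    zs = np.abs(zs)
    assert zs.max() < 4.0          # every cell within 4 MC standard errors
    assert zs.mean() < 2.0


def test_adjustment_identity_and_offset():
    ph = make_pheno(["T1"] * 4, [1.0, 2.0, 3.0, 4.0])
    d = fit_fixed_effects(ph, "oil")
    adj = adjust_phenotypes(ph, d)
    np.testing.assert_allclose(adj.records["ytilde"], ph["value"], atol=1e-10)
    # record in a cell with fitted offset +0.5 ends at y - 0.5
    ph2 = pd.concat([
        make_pheno(["T1"] * 10, list(np.arange(10.0) + 0.5)),
        make_pheno(["T2"] * 10, list(np.arange(10.0) - 0.5)),
    ], ignore_index=True)
    d2 = fit_fixed_effects(ph2, "oil")
    adj2 = adjust_phenotypes(ph2, d2)
    rec = adj2.records
    y = rec[rec.trial_id == "T1"].iloc[0]
    assert y["ytilde"] == pytest.approx(y["value"] - 0.5, abs=1e-8)


def test_accession_aggregate_is_mean_of_records():
    ph = pd.concat([
        make_pheno(["T1"] * 6, [1, 2, 3, 4, 5, 6.0], accessions=["a", "b", "c", "d", "e", "f"]),
        make_pheno(["T2"] * 6, [2, 3, 4, 5, 6, 7.0], accessions=["a", "b", "c", "d", "e", "f"]),
    ], ignore_index=True)
    d = fit_fixed_effects(ph, "oil")
    adj = adjust_phenotypes(ph, d)
    rec = adj.records
    a_vals = rec[rec.accession_id == "a"]["ytilde"]
    assert adj.by_accession["a"] == pytest.approx(a_vals.mean())


def test_refit_on_adjusted_gives_null_effects(small_collection):
    ph = small_collection.phenotypes
    d = fit_fixed_effects(ph, "protein")
    adj = adjust_phenotypes(ph, d)
    ph2 = adj.records.copy()
    ph2["value"] = ph2["ytilde"]
    d2 = fit_fixed_effects(ph2, "protein")
    assert d2.trial_effects.abs().max() < 1e-8
    assert max(abs(v) for v in d2.mg_effects.values()) < 1e-8


def test_constant_shift_moves_mu_only(small_collection):
    ph = small_collection.phenotypes
    d = fit_fixed_effects(ph, "oil")
    ph2 = ph.copy()
    ph2.loc[ph2.trait == "oil", "value"] += 5.0
    d2 = fit_fixed_effects(ph2, "oil")
    assert d2.mu - d.mu == pytest.approx(5.0, abs=1e-8)
    adj, adj2 = adjust_phenotypes(ph, d), adjust_phenotypes(ph2, d2)
    np.testing.assert_allclose(
        adj2.records["ytilde"] - d2.mu, adj.records["ytilde"] - d.mu, atol=1e-8
    )


def test_unseen_cell_rejected():
    ph = make_pheno(["T1"] * 4, [1.0, 2, 3, 4])
    d = fit_fixed_effects(ph, "oil")
    bad = make_pheno(["T2"] * 4, [1.0, 2, 3, 4])
    with pytest.raises(ValidationError, match="unseen"):
        adjust_phenotypes(pd.concat([ph, bad], ignore_index=True), d)


def test_covariate_records_dropped_and_fit():
    rng = np.random.default_rng(9)
    n = 60
    shat = rng.integers(1, 6, n).astype(float)
    y = 5.0 - 0.4 * shat + rng.normal(0, 0.1, n)
    shat[:5] = np.nan
    ph = make_pheno(["T1"] * n, y, shattering=shat, trait="yield")
    d = fit_fixed_effects(ph, "yield", ("shattering",))
    assert d.covariate_coefs["shattering"] == pytest.approx(-0.4, abs=0.05)


# ----------------------------------------------------------- heritability
def reps_frame(rng, n_acc, n_rep, s2a, s2e):
    a = rng.normal(0, np.sqrt(s2a), n_acc)
    rows = []
    for r in range(n_rep):
        for i in range(n_acc):
            rows.append((f"a{i}", r + 1, a[i] + rng.normal(0, np.sqrt(s2e))))
    return pd.DataFrame(rows, columns=["accession_id", "rep", "value"])


def test_h2_limits(rng):
    df = reps_frame(rng, 30, 3, 2.0, 0.0)
    df["value"] = df.groupby("accession_id")["value"].transform("mean")  # zero residual
    assert entry_mean_heritability(df) == pytest.approx(1.0, abs=1e-4)
    df2 = reps_frame(rng, 30, 3, 0.0, 1.0)
    assert entry_mean_heritability(df2) < 0.15


def test_h2_single_rep_errors(rng):
    df = reps_frame(rng, 10, 1, 1.0, 1.0)
    with pytest.raises(ValidationError, match="single rep"):
        entry_mean_heritability(df)


def test_h2_matches_closed_form():
    """sigma2_A = 3*sigma2_e with 4 reps gives H2 = 12/13 ~ 0.923."""
    vals = []
    for seed in range(10):
        rng = np.random.default_rng(100 + seed)
        df = reps_frame(rng, 200, 4, 3.0, 1.0)
        vals.append(entry_mean_heritability(df))
    assert np.mean(vals) == pytest.approx(12 / 13, abs=0.03)


def test_h2_affine_invariant(rng):
    df = reps_frame(rng, 80, 3, 2.0, 1.0)
    h = entry_mean_heritability(df)
    df2 = df.copy()
    df2["value"] = 3.5 * df2["value"] - 7.0
    assert entry_mean_heritability(df2) == pytest.approx(h, abs=1e-4)
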