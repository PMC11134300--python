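"""The synthetic-population generator and its planted structure."""
import dataclasses

import numpy as np
import pandas as pd
import pytest

from microtrans import community_matrix as cm
from microtrans.pedigree_kinship import additive_relationship
from microtrans.rfid_social import contact_matrix, parse_visits
from microtrans.simdata import (
    AgeProfile,
    SimConfig,
    simulate_counts,
    simulate_dataset,
    simulate_event_log,
    simulate_pedigree,
    simulate_visits,
)


def cfg(**kw):
    base = dict(n_founders_per_subspecies=8, max_individuals_per_subspecies=40,
                n_asv=40, depth_range=(500, 1500), visits_per_mouse=40,
                subspecies=("MMM",), sections=("colon",), seed=0)
    base.update(kw)
    return SimConfig(**base)


class TestSimulatePedigree:
    def test_zero_generations_yields_founders_only(self):
        ped = simulate_pedigree(cfg(max_generations=0))
        assert len(ped.ids) == 8
        assert ped.founders() == ped.ids

    def test_within_deme_mating_forced(self):
        ped = simulate_pedigree(cfg(p_within_deme_mating=1.0, seed=3))
        t = ped.table.set_index("id")
        offspring = t[t["dam"].notna()]
        assert len(offspring) > 0
        for _, r in offspring.iterrows():
            assert t.at[r["dam"], "deme"] == t.at[r["sire"], "deme"]

    def test_parents_precede_offspring_by_gestation(self):
        ped = simulate_pedigree(cfg(seed=4))
        t = ped.table.set_index("id")
        for _, r in t[t["dam"].notna()].iterrows():
            for p in (r["dam"], r["sire"]):
                assert r["birth_day"] - t.at[p, "birth_day"] >= 19

    def test_single_sex_founders_cannot_breed(self):
        config = cfg(n_founders_per_subspecies=1)
        with pytest.raises(ValueError, match="cannot breed"):
            simulate_pedigree(config)

    def test_poisson_litter_size_mean(self):
        """~10 000 litters at mean 6: the sample mean must fall within 3
        standard errors (small upward allowance for unobservable empty
        litters)."""
        # offspring stay immature within the horizon, so every litter is a
        # founder × founder mating and every female litters every cycle
        config = SimConfig(
            n_founders_per_subspecies=500, n_demes=5, experiment_length=125,
            litter_interval_days=5, p_litter_per_cycle=1.0,
            max_individuals_per_subspecies=10 ** 9,
            founder_age_at_release=10_000, maturity_age_days=5_000,
            litter_size_mean=6.0, subspecies=("MMM",), seed=5,
        )
        ped = simulate_pedigree(config)
        kids = ped.table[ped.table["dam"].notna()]
        litters = kids.groupby(["dam", "birth_day"]).size()
        assert len(litters) >= 5000
        se = np.sqrt(6.0 / len(litters))
        # truncation of unobservable zero litters inflates the mean by
        # 6·P(0)/(1-P(0)) ≈ 0.015
        assert abs(litters.mean() - 6.0) <= 3 * se + 0.02

    def test_no_cross_subspecies_matings(self):
        config = cfg(subspecies=("MMM", "MMD"), max_individuals_per_subspecies=30)
        ped = simulate_pedigree(config)
        t = ped.table.set_index("id")
        for _, r in t[t["dam"].notna()].iterrows():
            assert t.at[r["dam"], "subspecies"] == r["subspecies"]
            assert t.at[r["sire"], "subspecies"] == r["subspecies"]

    def test_parent_offspring_relatedness_half(self):
        ped = simulate_pedigree(cfg(seed=6))
        A = additive_relationship(ped)
        t = ped.table.set_index("id")
        checked = 0
        for _, r in t[t["dam"].notna()].iterrows():
            if t.at[r["dam"], "dam"] is None and A.loc(r.name, r.name) == 1.0:
                assert A.loc(r.name, r["dam"]) == pytest.approx(0.5)
                checked += 1
        assert checked > 0


class TestSimulateEvents:
    def test_single_visit_pattern(self):
        ped = simulate_pedigree(cfg(max_generations=0, n_founders_per_subspecies=2))
        config = cfg(max_generations=0, n_founders_per_subspecies=2,
                     visits_per_mouse=1)
        events = simulate_event_log(ped, config)
        by_mouse = pd.DataFrame([(e.mouse_id, e.reader, e.timestamp)
                                 for e in events],
                                columns=["mouse", "reader", "t"])
        for _, grp in by_mouse.groupby("mouse"):
            grp = grp.sort_values("t")
            for k in range(0, len(grp), 4):
                assert list(grp["reader"].iloc[k:k + 4]) == \
                    ["outer", "inner", "inner", "outer"]
                assert grp["t"].iloc[k:k + 4].is_monotonic_increasing

    def test_round_trip_identity_without_drops(self):
        config = cfg(seed=7)
        ped = simulate_pedigree(config)
        visits = simulate_visits(ped, config)
        events = simulate_event_log(ped, config, visits=visits)
        parsed, report = parse_visits(events)
        truth = sorted((v.mouse_id, v.nestbox_id, v.start, v.end) for v in visits)
        got = sorted((v.mouse_id, v.nestbox_id, v.start, v.end) for v in parsed)
        assert got == truth
        assert report.records_discarded == 0

    def test_empty_pedigree_empty_log(self):
        ped = simulate_pedigree(cfg(max_generations=0))
        empty = ped.table.iloc[0:0]
        from microtrans.pedigree_kinship import PedigreeTable

        events = simulate_event_log(PedigreeTable(empty), cfg())
        assert events == []

    def test_deme_preference_raises_within_deme_contact(self):
        """Across 20 replicate simulations, mean within-deme pairwise contact
        exceeds the between-deme mean."""
        within, between = [], []
        for seed in range(20):
            config = cfg(seed=100 + seed, max_generations=0,
                         n_founders_per_subspecies=12, deme_preference=0.9,
                         visits_per_mouse=60)
            ped = simulate_pedigree(config)
            visits = simulate_visits(ped, config)
            m = contact_matrix(visits, ped.ids)
            deme = ped.table.set_index("id")["deme"]
            ids = ped.ids
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    (within if deme[ids[i]] == deme[ids[j]] else between).append(
                        m.values[i, j])
        assert np.mean(within) > np.mean(between)


class TestSimulateCounts:
    def test_degenerate_config_shares_one_composition(self):
        config = cfg(w_vertical=0.0, w_social=0.0, sigma_individual=0.0,
                     depth_range=(5000, 5000), seed=8)
        ped = simulate_pedigree(config)
        contacts = contact_matrix(simulate_visits(ped, config), ped.ids)
        counts, meta, truth = simulate_counts(ped, contacts, config)
        comps = truth.latent_compositions.to_numpy()
        np.testing.assert_allclose(comps, np.broadcast_to(comps[0], comps.shape),
                                   atol=1e-12)
        S = cm.dissimilarity(counts, "bray_curtis")
        off = S.values[~np.eye(len(S.values), dtype=bool)]
        assert off.min() > 0.9  # only multinomial noise away from 1

    def test_column_sums_equal_drawn_depth(self):
        config = cfg(seed=9)
        ped = simulate_pedigree(config)
        contacts = contact_matrix(simulate_visits(ped, config), ped.ids)
        counts, _, _ = simulate_counts(ped, contacts, config)
        depths = counts.depths()
        assert depths.between(*config.depth_range).all()

    def test_asymmetric_contacts_rejected(self):
        config = cfg()
        ped = simulate_pedigree(config)
        from microtrans.rfid_social import ContactMatrix

        n = len(ped.ids)
        with pytest.raises(ValueError, match="symmetric"):
            bad = ContactMatrix(ped.ids, np.triu(np.ones((n, n)), 1))
            simulate_counts(ped, bad, config)

    def test_vertical_transmission_raises_parent_offspring_similarity(self):
        """10 replicates: parent–offspring Bray–Curtis similarity exceeds the
        unrelated-pair mean when transmission is purely vertical."""
        po_means, un_means = [], []
        for seed in range(10):
            config = cfg(seed=200 + seed, w_vertical=4.0, w_social=0.0,
                         w_env=1.0, sigma_individual=0.25,
                         age_profile=AgeProfile(weaning_age=5, peak_age=60,
                                                decay_rate=0.002))
            ped = simulate_pedigree(config)
            contacts = contact_matrix(simulate_visits(ped, config), ped.ids)
            counts, meta, _ = simulate_counts(ped, contacts, config)
            S = cm.dissimilarity(counts, "bray_curtis")
            sidx = {s: i for i, s in enumerate(S.sample_ids)}
            t = ped.table.set_index("id")
            A = additive_relationship(ped)
            po, un = [], []
            ids = ped.ids
            for a in range(len(ids)):
                for b in range(a + 1, len(ids)):
                    i, j = ids[a], ids[b]
                    sim = S.values[sidx[f"{i}:colon"], sidx[f"{j}:colon"]]
                    if t.at[j, "dam"] == i or t.at[j, "sire"] == i or \
                            t.at[i, "dam"] == j or t.at[i, "sire"] == j:
                        po.append(sim)
                    elif A.loc(i, j) == 0.0:
                        un.append(sim)
            po_means.append(np.mean(po))
            un_means.append(np.mean(un))
        assert np.mean(po_means) > np.mean(un_means)

    def test_social_weight_increases_contact_similarity_correlation(self):
        """The dyadic correlation between contact time and microbiota
        similarity grows with w_social (mean over 10 replicates)."""
        corrs = {0.0: [], 4.0: []}
        for seed in range(10):
            base = cfg(seed=300 + seed, w_vertical=0.0, w_env=1.0,
                       sigma_individual=0.3, visits_per_mouse=80)
            ped = simulate_pedigree(base)
            contacts = contact_matrix(simulate_visits(ped, base), ped.ids)
            for w in corrs:
                config = dataclasses.replace(base, w_social=w)
                counts, _, _ = simulate_counts(ped, contacts, config)
                S = cm.dissimilarity(counts, "bray_curtis")
                sidx = {s: i for i, s in enumerate(S.sample_ids)}
                ids = ped.ids
                sims, cons = [], []
                for a in range(len(ids)):
                    for b in range(a + 1, len(ids)):
                        sims.append(S.values[sidx[f"{ids[a]}:colon"],
                                             sidx[f"{ids[b]}:colon"]])
                        cons.append(contacts.values[a, b])
                corrs[w].append(np.corrcoef(cons, sims)[0, 1])
        assert np.mean(corrs[4.0]) > np.mean(corrs[0.0])


class TestDeterminism:
    def test_bit_identical_outputs_for_fixed_seed(self):
        config = cfg(seed=12, drop_fraction=0.05)
        d1 = simulate_dataset(config)
        d2 = simulate_dataset(config)
        assert d1.counts.counts.equals(d2.counts.counts)
        assert [dataclasses.astuple(e) for e in d1.events] == \
            [dataclasses.astuple(e) for e in d2.events]
        assert d1.pedigree.table.equals(d2.pedigree.table)

    def test_weights_validation(self):
        with pytest.raises(ValueError, match="positive"):
            cfg(w_vertical=0.0, w_social=0.0, w_env=0.0)
        with pytest.raises(ValueError, match="probability"):
            cfg(p_within_deme_mating=1.5)
        with pytest.raises(ValueError, match="depth_range"):
            cfg(depth_range=(0, 10))
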