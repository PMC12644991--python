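import numpy as np
import pytest

from fwalign.alignment import Alignment, GAParams, align_replicated, s3_score
from fwalign.foodweb import FoodWeb, SpeciesRecord, TrophicLink
from fwalign.metrics import metrics_table
from fwalign.rewiring import (aligned_region_summary, classify_links,
                              link_class_table, rewiring_per_species,
                              species_turnover)
from fwalign.synthetic import GeneratorParams, apply_drought, niche_model_web

from conftest import make_web


def drop_species(web, sid, web_id="d", treatment="drought"):
    return FoodWeb(
        web_id, treatment, web.block,
        [r for r in web.species.values() if r.species_id != sid],
        [l for l in web.links.values() if sid not in l.pair],
    )


def as_drought(web):
    return FoodWeb("d", "drought", web.block,
                   list(web.species.values()), list(web.links.values()))


class TestTurnover:
    def test_identical_webs(self, toy_web):
        t = species_turnover(toy_web, as_drought(toy_web))
        assert (t.prop_shared_species, t.prop_shared_links) == (1.0, 1.0)
        assert (t.n_extinct_consumers, t.n_invaders) == (0, 0)

    def test_single_consumer_extinction(self, toy_web):
        d = drop_species(toy_web, "pred")
        t = species_turnover(toy_web, d)
        assert t.prop_shared_species == 1.0  # all drought species in control
        assert t.prop_shared_links == 1.0
        assert t.n_extinct_consumers == 1
        back = species_turnover(d, as_drought(toy_web))
        assert back.prop_shared_species < 1.0

    def test_generator_targets_recovered(self):
        """Defaults plant 92% shared species / 60% shared links."""
        params = GeneratorParams(seed=42)
        rng = np.random.default_rng(0)
        sp, sl = [], []
        for k in range(12):
            web = niche_model_web(74, params.C_target, seed=int(rng.integers(2**31)))
            pair = apply_drought(web, params, seed=int(rng.integers(2**31)))
            t = species_turnover(pair.control, pair.drought)
            sp.append(t.prop_shared_species)
            sl.append(t.prop_shared_links)
        assert np.mean(sp) == pytest.approx(0.92, abs=0.02)
        assert np.mean(sl) == pytest.approx(0.60, abs=0.05)


class TestClassification:
    def test_partition_identities(self, small_pair):
        cls = classify_links(small_pair.control, small_pair.drought)
        ld = small_pair.drought.link_pairs()
        lc = small_pair.control.link_pairs()
        assert cls.conserved | cls.rewired | cls.invader_links == ld
        assert len(cls.conserved) + len(cls.rewired) + len(cls.invader_links) == len(ld)
        assert cls.conserved | cls.lost == lc
        assert len(cls.conserved) + len(cls.lost) == len(lc)

    def test_surviving_consumer_new_link_is_rewired(self, toy_web):
        d = make_web(web_id="d", treatment="drought",
                     links=[("det1", "shred"), ("det2", "shred"),
                            ("alg1", "graz"), ("graz", "pred"),
                            ("shred", "pred"), ("alg1", "shred")])
        cls = classify_links(toy_web, d)
        assert ("alg1", "shred") in cls.rewired

    def test_planted_rewired_set_recovered_exactly(self, small_pair, default_pair):
        for pair in (small_pair, default_pair):
            cls = classify_links(pair.control, pair.drought)
            assert cls.rewired == pair.truth.rewired
            invader_consumers = {c for (_, c) in cls.invader_links}
            assert invader_consumers <= pair.truth.invaders

    def test_long_table_covers_all_links(self, small_pair):
        cls = classify_links(small_pair.control, small_pair.drought)
        table = link_class_table(cls)
        assert len(table) == (len(cls.conserved) + len(cls.lost)
                              + len(cls.rewired) + len(cls.invader_links))
        assert set(table["link_class"]) <= {"conserved", "lost", "rewired", "invader"}


class TestPerSpecies:
    def test_identical_diet_means_zero_rewiring(self, toy_web):
        sp = rewiring_per_species(toy_web, as_drought(toy_web))
        assert (sp["n_rewired"] == 0).all()
        assert (sp["prop_rewired"] == 0.0).all()

    def test_entirely_new_diet_is_prop_one(self, toy_web):
        d = make_web(web_id="d", treatment="drought",
                     links=[("det1", "shred"), ("det2", "shred"),
                            ("alg1", "graz"), ("det1", "pred"), ("det2", "pred")])
        sp = rewiring_per_species(toy_web, d).set_index("species_id")
        assert sp.loc["pred", "prop_rewired"] == 1.0

    def test_rewired_counts_sum_matches_classification(self, small_pair):
        cls = classify_links(small_pair.control, small_pair.drought)
        sp = rewiring_per_species(small_pair.control, small_pair.drought, cls)
        # every rewired link has a surviving consumer with a nonempty diet
        assert sp["n_rewired"].sum() == len(cls.rewired)

    def test_metric_deltas_are_drought_minus_control(self, small_pair):
        mc = metrics_table(small_pair.control.to_undirected())
        md = metrics_table(small_pair.drought.to_undirected())
        sp = rewiring_per_species(small_pair.control, small_pair.drought,
                                  metrics_c=mc, metrics_d=md)
        row = sp.iloc[0]
        sid = row["species_id"]
        dc = mc.set_index("species_id").loc[sid, "degree"]
        dd = md.set_index("species_id").loc[sid, "degree"]
        assert row["delta_degree"] == dd - dc

    def test_specialist_bias_gives_negative_degree_slope(self):
        """Pooled over pairs, prop_rewired declines with control degree."""
        params = GeneratorParams(seed=17, specialist_bias=2.0)
        rng = np.random.default_rng(3)
        rows = []
        for _ in range(8):
            web = niche_model_web(74, params.C_target, seed=int(rng.integers(2**31)))
            pair = apply_drought(web, params, seed=int(rng.integers(2**31)))
            sp = rewiring_per_species(pair.control, pair.drought)
            rows.append(sp)
        import pandas as pd
        sp = pd.concat(rows)
        slope = np.polyfit(sp["n_links_control"], sp["prop_rewired"], 1)[0]
        assert slope < 0


class TestAlignedRegion:
    GA = GAParams(population_size=80, generations=80, elite_fraction=0.5, n_runs=1)

    def test_full_alignment_reproduces_whole_connectance(self, toy_web):
        d = as_drought(toy_web)
        G = toy_web.to_undirected()
        rep = align_replicated(G, d.to_undirected(), GAParams(
            population_size=60, generations=40, elite_fraction=0.5, n_runs=1, seed=0))
        s = aligned_region_summary(toy_web, d, rep.best)
        assert s.connectance_aligned_c == pytest.approx(s.connectance_whole_c)

    def test_dense_subregion_raises_connectance(self):
        """An alignment onto a dense core exceeds whole-web connectance."""
        core = ["a", "b", "c", "d"]
        periph = [f"p{i}" for i in range(6)]
        species = ([("det1", "detritus", None), ("det2", "detritus", None)]
                   + [(s, "predator", 1.0) for s in core]
                   + [(s, "primary_producer", 1.0) for s in periph])
        links = [("det1", c) for c in core] + [("det2", c) for c in core]
        links += [(r, c) for r in core for c in core if r < c]
        web = make_web(species=species, links=links)
        mapping = {x: x for x in core + ["det1", "det2"]}
        aln = Alignment(mapping=mapping, conserved_edges=frozenset(), s3=1.0)
        s = aligned_region_summary(web, as_drought(web), aln)
        assert s.connectance_aligned_c > s.connectance_whole_c

    def test_downscaled_drought_fluxes(self, default_pair):
        Gd = default_pair.drought.to_undirected()
        Gc = default_pair.control.to_undirected()
        rep = align_replicated(Gd, Gc, self.GA)
        s = aligned_region_summary(default_pair.control, default_pair.drought,
                                   rep.best)
        assert s.total_flux_aligned_c is not None
        assert s.total_flux_d is not None
        assert s.total_flux_d < s.total_flux_aligned_c
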