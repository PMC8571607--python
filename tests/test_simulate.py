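"""Generator correctness: trees, sequence evolution, transmission, I/O."""

import numpy as np
import pytest
from scipy import stats

from endosym.seqdist import distance_matrix, p_distance
from endosym.simulate import (
    InvalidConfigError,
    SimulationConfig,
    Tree,
    emit_dataset,
    evolve_sequences,
    load_dataset,
    simulate_host_tree,
    simulate_transmission,
)


class TestHostTree:
    def test_three_tips_shape(self):
        t = simulate_host_tree(3, seed=0)
        assert len(t.leaf_names()) == 3
        assert t.n_internal() == 2

    def test_determinism(self):
        a = simulate_host_tree(12, seed=5).newick()
        b = simulate_host_tree(12, seed=5).newick()
        assert a == b

    def test_ultrametric_unit_depth(self):
        t = simulate_host_tree(10, seed=2)
        names, D = t.tip_distances()

        def tip_depth(node, acc=0.0):
            if node.is_leaf:
                return {node.name: acc}
            out = {}
            for c in node.children:
                out.update(tip_depth(c, acc + c.length))
            return out

        depths = tip_depth(t)
        assert all(abs(d - 1.0) < 1e-9 for d in depths.values())

    def test_cherry_count_matches_independent_yule_oracle(self):
        # independent oracle: topology-only Yule split process
        def oracle_cherries(n, rng):
            children = {0: []}
            active = [0]
            nxt = 1
            while len(active) < n:
                i = active.pop(rng.integers(len(active)))
                kids = [nxt, nxt + 1]
                nxt += 2
                children[i] = kids
                for k in kids:
                    children[k] = []
                    active.append(k)
            return sum(
                1
                for k, v in children.items()
                if len(v) == 2 and all(not children[c] for c in v)
            )

        n, reps = 50, 400
        rng = np.random.default_rng(7)
        ours = [
            simulate_host_tree(n, seed=s).n_cherries() for s in range(reps)
        ]
        orc = [oracle_cherries(n, rng) for _ in range(reps)]
        se = np.sqrt(np.var(ours, ddof=1) / reps + np.var(orc, ddof=1) / reps)
        assert abs(np.mean(ours) - np.mean(orc)) < 3 * se

    def test_too_few_hosts_rejected(self):
        with pytest.raises(InvalidConfigError):
            simulate_host_tree(2, seed=0)


class TestEvolveSequences:
    def test_zero_rate_identity(self):
        t = simulate_host_tree(5, seed=1)
        tips = evolve_sequences(t, "ACGT" * 25, 0.0, seed=0)
        assert all(s == "ACGT" * 25 for s in tips.values())

    def test_determinism(self):
        t = simulate_host_tree(5, seed=1)
        a = evolve_sequences(t, "ACGT" * 25, 0.1, seed=9)
        b = evolve_sequences(t, "ACGT" * 25, 0.1, seed=9)
        assert a == b

    def test_transition_probability_closed_form(self):
        # two tips separated by total path t: expected p-distance is the
        # model's transition probability (3/4)(1 - e^{-4t/3})
        t_total = 0.3
        root = Tree(None)
        root.children = [
            Tree("a", t_total / 2), Tree("b", t_total / 2)
        ]
        rng = np.random.default_rng(3)
        base = "".join(rng.choice(list("ACGT"), size=10_000))
        tips = evolve_sequences(root, base, 1.0, seed=4)
        expected = 0.75 * (1 - np.exp(-4 * t_total / 3))
        obs = p_distance(tips["a"], tips["b"]).p
        se = np.sqrt(expected * (1 - expected) / 10_000)
        assert abs(obs - expected) < 3 * se

    def test_non_acgt_root_rejected(self):
        t = simulate_host_tree(3, seed=0)
        with pytest.raises(ValueError, match="non-ACGT"):
            evolve_sequences(t, "ACGX", 0.1, seed=0)


class TestTransmission:
    def test_pure_vertical_log_and_codivergence(self, small_community):
        ds = small_community
        assert all(
            ev.event == "vertical" for ev in ds.truth.transfer_log
        )
        # symbiont divergence is a monotone function of host divergence
        concat = {
            h: "".join(
                ds.community_seqs[l][s] for l in ds.config.locus_names
            )
            for h, s in ds.truth.assignments.items()
        }
        hd = distance_matrix(ds.host_marker)
        sd = distance_matrix({h: concat[h] for h in hd.labels})
        iu = np.triu_indices(hd.n, k=1)
        rho = stats.spearmanr(hd.values[iu], sd.values[iu])[0]
        assert rho > 0.5

    def test_within_only_strains_traceable(self):
        cfg = SimulationConfig(n_hosts=12, seed=8, h_within=1.0)
        ds = simulate_transmission(cfg)
        counts = {}
        for s in ds.truth.assignments.values():
            counts[s] = counts.get(s, 0) + 1
        donors = {
            ev.recipient: ev.donor
            for ev in ds.truth.transfer_log
            if ev.event == "within"
        }
        assert len(donors) == cfg.n_hosts
        for host, strain in ds.truth.assignments.items():
            assert counts[strain] >= 2 or host in donors

    def test_forced_recombination_logged_once_per_acquisition(self):
        cfg = SimulationConfig(
            n_hosts=10, seed=9, h_within=0.5, g_global=0.5, rho=1.0
        )
        ds = simulate_transmission(cfg)
        n_acq = sum(
            ev.event != "vertical" for ev in ds.truth.transfer_log
        )
        assert len(ds.truth.recomb_log) == n_acq
        lengths = dict(zip(cfg.locus_names, cfg.locus_lengths))
        for rec in ds.truth.recomb_log:
            assert 1 <= rec.start <= rec.end <= lengths[rec.locus]

    def test_recombinant_sequence_is_true_mosaic(self):
        cfg = SimulationConfig(
            n_hosts=10, seed=13, g_global=1.0, rho=1.0
        )
        ds = simulate_transmission(cfg)
        assert ds.truth.recomb_log
        for rec in ds.truth.recomb_log:
            if rec.strain_id not in ds.community_seqs[rec.locus]:
                continue  # recombinant displaced by a later acquisition
            seq = ds.community_seqs[rec.locus][rec.strain_id]
            seg = slice(rec.start - 1, rec.end)
            # some pool strain provides the backbone outside the segment
            backbone_match = any(
                p[: seg.start] == seq[: seg.start]
                and p[rec.end :] == seq[rec.end :]
                for p in ds.pool_seqs[rec.locus].values()
            )
            assert backbone_match

    def test_invalid_rates_rejected(self):
        with pytest.raises(InvalidConfigError):
            SimulationConfig(h_within=0.7, g_global=0.7)
        with pytest.raises(InvalidConfigError):
            SimulationConfig(n_hosts=2)
        with pytest.raises(InvalidConfigError):
            SimulationConfig(rho=1.5)

    def test_full_determinism(self):
        cfg = SimulationConfig(
            n_hosts=8, seed=77, h_within=0.3, g_global=0.2, rho=0.5
        )
        a = simulate_transmission(cfg)
        b = simulate_transmission(cfg)
        assert a.truth.assignments == b.truth.assignments
        assert a.community_seqs == b.community_seqs
        assert a.truth.host_tree.newick() == b.truth.host_tree.newick()


class TestEmitLoad:
    def test_round_trip(self, tmp_path):
        cfg = SimulationConfig(
            n_hosts=6, seed=3, h_within=0.4, rho=0.6, pool_size=9
        )
        ds = simulate_transmission(cfg)
        out = emit_dataset(ds, tmp_path / "d")
        back = load_dataset(out)
        assert back.truth.assignments == ds.truth.assignments
        assert back.community_seqs == ds.community_seqs
        assert back.pool_seqs == ds.pool_seqs
        assert back.pool_supergroups == ds.pool_supergroups
        assert back.host_marker == ds.host_marker
        assert back.truth.transfer_log == ds.truth.transfer_log
        assert back.truth.recomb_log == ds.truth.recomb_log
        # serialising again is byte-identical
        out2 = emit_dataset(back, tmp_path / "d2")
        for f in sorted(p.name for p in out.iterdir()):
            assert (out / f).read_bytes() == (out2 / f).read_bytes()

    def test_headers_carry_host_and_strain(self, tmp_path):
        cfg = SimulationConfig(n_hosts=5, seed=4, pool_size=9)
        ds = simulate_transmission(cfg)
        out = emit_dataset(ds, tmp_path)
        first_locus = cfg.locus_names[0]
        text = (out / f"community_{first_locus}.fasta").read_text()
        headers = [l[1:] for l in text.splitlines() if l.startswith(">")]
        for h in headers:
            host, strain = h.split("|")
            assert ds.truth.assignments[host] == strain

    def test_record_counts(self, tmp_path):
        cfg = SimulationConfig(n_hosts=20, seed=5)
        ds = simulate_transmission(cfg)
        out = emit_dataset(ds, tmp_path)
        for locus in cfg.locus_names:
            text = (out / f"community_{locus}.fasta").read_text()
            assert text.count(">") == 20
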