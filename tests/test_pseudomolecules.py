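import numpy as np
import pandas as pd
import pytest

from homoeolog import pseudomolecules as pm
from homoeolog import synthetic_data as sd


def _model_world(n_genes, n_blocks, seed):
    cfg = sd.SimConfig(n_triplets=n_genes, seed=seed, private_fraction=0.0)
    a, b, d, truth = sd.simulate_subgenomes(cfg)
    model_table, block_map = sd.simulate_rearranged_reference(
        truth, n_blocks, seed=seed
    )
    return a, truth, model_table, block_map


def _anchors_from_truth(model_table, block_map):
    rows = []
    for _, r in block_map.iterrows():
        sub = model_table.iloc[r.model_gene_start : r.model_gene_end]
        rows.append(
            dict(
                block_id=r.block_id,
                chrom="Bd1",
                anchor_start=int(sub["start"].min()),
                anchor_end=int(sub["end"].max()),
            )
        )
    return pd.DataFrame(rows)


def _true_map_positions(model_table, truth):
    wheat = {g: i for i, g in enumerate(truth.true_order)}
    return pd.DataFrame(
        dict(
            chrom="Bd1",
            coord=model_table["start"].to_numpy(),
            linkage_group="LG1",
            bin_position=[wheat[g[3:]] for g in model_table["gene_id"]],
        )
    )


class TestSplitReference:
    def test_midpoint_cut(self):
        model = pd.DataFrame(
            dict(
                gene_id=["g1", "g2"],
                chrom=["c", "c"],
                start=[100, 2100],
                end=[900, 2900],
                strand=["+", "+"],
            )
        )
        anchors = pd.DataFrame(
            dict(
                block_id=["b1", "b2"],
                chrom=["c", "c"],
                anchor_start=[100, 2000],
                anchor_end=[1000, 2900],
            )
        )
        blocks, assigned = pm.split_reference(model, anchors)
        assert blocks[0].end == 1500  # floor((1000 + 2000) / 2)
        assert blocks[1].start == 1500
        assert list(assigned["block_id"]) == ["b1", "b2"]

    def test_single_block_no_cuts(self):
        model = pd.DataFrame(
            dict(gene_id=["g1"], chrom=["c"], start=[0], end=[10], strand=["+"])
        )
        anchors = pd.DataFrame(
            dict(block_id=["b"], chrom=["c"], anchor_start=[0], anchor_end=[10])
        )
        blocks, assigned = pm.split_reference(model, anchors)
        assert len(blocks) == 1
        assert (assigned["block_id"] == "b").all()

    def test_overlapping_anchors_rejected(self):
        model = pd.DataFrame(
            dict(gene_id=["g"], chrom=["c"], start=[0], end=[10], strand=["+"])
        )
        anchors = pd.DataFrame(
            dict(
                block_id=["b1", "b2"],
                chrom=["c", "c"],
                anchor_start=[0, 5],
                anchor_end=[10, 20],
            )
        )
        with pytest.raises(ValueError, match="overlap"):
            pm.split_reference(model, anchors)

    def test_partition_matches_simulated_truth(self):
        _, truth, model_table, block_map = _model_world(200, 9, seed=41)
        anchors = _anchors_from_truth(model_table, block_map)
        blocks, assigned = pm.split_reference(model_table, anchors)
        assert assigned["block_id"].notna().all()
        for _, r in block_map.iterrows():
            sub = assigned.iloc[r.model_gene_start : r.model_gene_end]
            assert (sub["block_id"] == r.block_id).all()


class TestOrderSegments:
    def test_identity_fixture_preserves_order(self):
        _, truth, model_table, block_map = _model_world(50, 1, seed=42)
        anchors = _anchors_from_truth(model_table, block_map)
        blocks, assigned = pm.split_reference(model_table, anchors)
        blocks = pm.assign_bin_spans(blocks, _true_map_positions(model_table, truth))
        out = pm.order_segments(blocks, assigned)
        got = [g[3:] for g in out["LG1"].gene_order["gene_id"]]
        assert got == list(truth.true_order)

    def test_round_trip_recovers_true_order_exactly(self):
        _, truth, model_table, block_map = _model_world(300, 14, seed=43)
        anchors = _anchors_from_truth(model_table, block_map)
        blocks, assigned = pm.split_reference(model_table, anchors)
        blocks = pm.assign_bin_spans(blocks, _true_map_positions(model_table, truth))
        out = pm.order_segments(blocks, assigned)
        got = [g[3:] for g in out["LG1"].gene_order["gene_id"]]
        assert got == list(truth.true_order)
        # coordinates strictly increasing, every block used once
        coords = out["LG1"].gene_order["coordinate"].to_numpy()
        assert (np.diff(coords) > 0).all()
        used = [b.block_id for b in out["LG1"].blocks]
        assert len(used) == len(set(used)) == 14


class TestPlaceUnigenes:
    def test_identical_unigene_placed_at_gene_position(self):
        rng = np.random.default_rng(0)
        genes = {
            f"Bd_g{i}": "".join(rng.choice(list("ACGT"), size=300))
            for i in range(5)
        }
        positions = pd.DataFrame(
            dict(
                gene_id=list(genes),
                pseudomolecule="LG1",
                position=range(5),
            )
        )
        unigenes = {"A_g3": genes["Bd_g3"]}
        placed, unplaced = pm.place_unigenes(unigenes, genes, positions)
        assert unplaced == []
        assert placed.loc[0, "position"] == 3
        assert placed.loc[0, "genome"] == "A"

    def test_random_sequence_is_unplaced(self):
        rng = np.random.default_rng(1)
        genes = {"Bd_g0": "".join(rng.choice(list("ACGT"), size=300))}
        positions = pd.DataFrame(
            dict(gene_id=["Bd_g0"], pseudomolecule="LG1", position=[0])
        )
        junk = {"A_x": "".join(rng.choice(list("ACGT"), size=300))}
        placed, unplaced = pm.place_unigenes(junk, genes, positions)
        assert len(placed) == 0 and unplaced == ["A_x"]


class TestReduceRedundancy:
    def _table(self, rows):
        return pd.DataFrame(
            rows,
            columns=[
                "unigene_id", "genome", "model_gene", "pseudomolecule",
                "position", "length",
            ],
        )

    def test_longest_wins(self):
        t = self._table(
            [
                ("u1", "A", "Bd_g1", "LG1", 0, 800),
                ("u2", "A", "Bd_g1", "LG1", 0, 1200),
            ]
        )
        out = pm.reduce_redundancy(t)
        assert list(out["unigene_id"]) == ["u2"]

    def test_unique_loci_unchanged(self):
        t = self._table(
            [
                ("u1", "A", "Bd_g1", "LG1", 0, 800),
                ("u2", "A", "Bd_g2", "LG1", 1, 500),
                ("u3", "B", "Bd_g1", "LG1", 0, 700),
            ]
        )
        out = pm.reduce_redundancy(t)
        assert len(out) == 3

    def test_splice_forms_collapse_matches_groupby_oracle(self):
        rng = np.random.default_rng(2)
        rows = []
        for i in range(30):
            locus = int(rng.integers(10))
            rows.append(
                (f"u{i:02d}", "A", f"Bd_g{locus}", "LG1", locus,
                 int(rng.integers(300, 1500)))
            )
        t = self._table(rows)
        out = pm.reduce_redundancy(t)
        oracle = t.groupby(["genome", "model_gene", "pseudomolecule", "position"])
        assert len(out) == oracle.ngroups
        for _, grp in oracle:
            longest = grp.sort_values(
                ["length", "unigene_id"], ascending=[False, True]
            ).iloc[0]
            assert longest["unigene_id"] in set(out["unigene_id"])

    def test_idempotent_and_never_grows(self):
        rng = np.random.default_rng(3)
        rows = [
            (f"u{i}", "A", f"Bd_g{int(rng.integers(5))}", "LG1", 0,
             int(rng.integers(100, 999)))
            for i in range(20)
        ]
        t = self._table(rows)
        once = pm.reduce_redundancy(t)
        twice = pm.reduce_redundancy(once)
        assert len(once) <= len(t)
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True)
        )

    def test_empty_table(self):
        t = self._table([])
        assert len(pm.reduce_redundancy(t)) == 0


class TestDotplot:
    def test_identical_orders_tau_one(self, tmp_path):
        order = {f"g{i}": i for i in range(20)}
        fig, tau = pm.collinearity_dotplot(
            order, order, path=tmp_path / "dot.png"
        )
        assert tau == 1.0
        assert (tmp_path / "dot.png").exists()

    def test_reversed_orders_tau_minus_one(self):
        order = {f"g{i}": i for i in range(20)}
        rev = {f"g{i}": 19 - i for i in range(20)}
        _, tau = pm.collinearity_dotplot(order, rev)
        assert tau == -1.0

    def test_inversion_lowers_tau(self):
        order = {f"g{i}": i for i in range(30)}
        inv = dict(order)
        for i in range(10, 20):
            inv[f"g{i}"] = 29 - i
        _, tau = pm.collinearity_dotplot(order, inv)
        assert 0 < tau < 1.0

    def test_disjoint_orders_raise(self):
        with pytest.raises(ValueError):
            pm.collinearity_dotplot({"a": 0}, {"b": 0})
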