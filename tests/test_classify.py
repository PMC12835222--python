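import numpy as np
import pandas as pd
import pytest

from hemidiff.classify import classify_genes, cross_dataset_compare, summarize_classes


def _tables():
    """Six genes constructed to hit every class exactly once."""
    genes = [f"g{i}" for i in range(6)]
    dis = pd.DataFrame(
        {
            "gene_id": genes,
            "log2fc": [1.0, 1.0, 1.0, 0.1, 2.0, 0.3],
            "fdr": [0.01, 0.01, 0.01, 0.50, 0.50, 0.50],
        }
    )
    asym = pd.DataFrame(
        {
            "gene_id": genes,
            "log2fc": [0.8, -0.9, 0.2, 0.9, 0.3, 0.4],
            "fdr": [0.01, 0.01, 0.90, 0.01, 0.50, 0.01],
        }
    )
    return dis, asym


EXPECTED = {
    "g0": "both_same_direction",      # both significant, same sign
    "g1": "both_opposite_direction",  # both significant, opposite sign
    "g2": "disease_only_stable",      # disease significant only
    "g3": "asym_only_differential",   # asym only, |delta lfc| = 0.8 >= 0.5
    "g4": "neither",                  # neither contrast significant
    "g5": "neither",                  # asym significant but delta 0.1 < 0.5
}


def test_hand_constructed_classes():
    dis, asym = _tables()
    table = classify_genes(dis, asym)
    got = dict(zip(table["gene_id"], table["gene_class"]))
    assert got == EXPECTED


def test_all_asym_null_kills_asym_classes():
    dis, asym = _tables()
    asym["fdr"] = 1.0
    table = classify_genes(dis, asym)
    assert not table["gene_class"].isin(
        ["both_same_direction", "both_opposite_direction", "asym_only_differential"]
    ).any()


def test_classes_partition_gene_universe():
    dis, asym = _tables()
    table = classify_genes(dis, asym)
    assert len(table) == 6
    assert table["gene_class"].notna().all()


def test_delta_threshold_gates_asym_only():
    dis, asym = _tables()
    table = classify_genes(dis, asym, delta=0.9)
    got = dict(zip(table["gene_id"], table["gene_class"]))
    assert got["g3"] == "neither"  # |0.1 - 0.9| = 0.8 < 0.9


def test_mismatched_universes_rejected():
    dis, asym = _tables()
    with pytest.raises(ValueError, match="differ by"):
        classify_genes(dis, asym.iloc[:-1])


def _random_tables(rng, n):
    genes = [f"g{i}" for i in range(n)]
    mk = lambda: pd.DataFrame(
        {
            "gene_id": genes,
            "log2fc": rng.normal(size=n),
            "fdr": rng.uniform(size=n),
        }
    )
    return mk(), mk()


def test_summary_fractions_equal_brute_force_on_random_tables():
    rng = np.random.default_rng(0)
    dis, asym = _random_tables(rng, 10_000)
    table = classify_genes(dis, asym)
    summary = summarize_classes(table)
    # independent recount by explicit looping over the merged rows
    d = dis.set_index("gene_id")
    a = asym.set_index("gene_id")
    n_asym = n_both = n_same = n_opp = 0
    for g in d.index:
        asym_sig = a.loc[g, "fdr"] < 0.05
        dis_sig = d.loc[g, "fdr"] < 0.05
        if asym_sig:
            n_asym += 1
            if dis_sig:
                n_both += 1
                prod = np.sign(d.loc[g, "log2fc"]) * np.sign(a.loc[g, "log2fc"])
                if prod > 0:
                    n_same += 1
                elif prod < 0:
                    n_opp += 1
    assert summary["n_asym_significant"] == n_asym
    assert summary["n_both_significant"] == n_both
    assert summary["frac_asym_also_disease"] == n_both / n_asym
    assert summary["frac_same_direction"] == n_same / (n_same + n_opp)
    assert summary["frac_opposite_direction"] == n_opp / (n_same + n_opp)


def test_fdr_monotonicity_of_significant_union():
    rng = np.random.default_rng(1)
    dis, asym = _random_tables(rng, 2000)
    active = lambda t: set(
        t.loc[t["gene_class"] != "neither", "gene_id"]
    ) - set(t.loc[t["gene_class"] == "asym_only_differential", "gene_id"])
    strict = classify_genes(dis, asym, fdr=0.02)
    loose = classify_genes(dis, asym, fdr=0.10)
    strict_sig = set(
        strict.loc[strict["asym_significant"] | strict["disease_significant"], "gene_id"]
    )
    loose_sig = set(
        loose.loc[loose["asym_significant"] | loose["disease_significant"], "gene_id"]
    )
    assert strict_sig.issubset(loose_sig)


def test_negating_asym_swaps_direction_classes():
    rng = np.random.default_rng(2)
    dis, asym = _random_tables(rng, 2000)
    flipped = asym.assign(log2fc=-asym["log2fc"])
    a = classify_genes(dis, asym).set_index("gene_id")["gene_class"]
    b = classify_genes(dis, flipped).set_index("gene_id")["gene_class"]
    swap = {
        "both_same_direction": "both_opposite_direction",
        "both_opposite_direction": "both_same_direction",
    }
    both = a.index[a.isin(swap) | b.isin(swap)]
    assert (b[both] == a[both].map(swap)).all()


def test_recovered_classes_match_truth_at_strong_effects(two_stage7, cohort7):
    """With unit planted effects the recovered cross-contrast classes agree
    with the planted ones for most effect genes."""
    _, _, truth = cohort7
    table = classify_genes(two_stage7.de_disease, two_stage7.de_asymmetry)
    merged = table.merge(truth.genes, on="gene_id")
    mapping = {
        "both_concordant": "both_same_direction",
        "both_discordant": "both_opposite_direction",
    }
    both = merged[merged["class_true"].isin(mapping)]
    hit = (
        both["gene_class"] == both["class_true"].map(mapping)
    ) | (both["gene_class"].isin(["disease_only_stable", "neither", "asym_only_differential"]))
    # direction agreement among doubly recovered genes is what matters
    directed = both[both["gene_class"].str.startswith("both_")]
    agree = (directed["gene_class"] == directed["class_true"].map(mapping)).mean()
    assert agree >= 0.85


def test_cross_dataset_empty_map_and_full_concordance():
    human = pd.DataFrame({"gene_id": ["TCP1", "BEX1"], "direction": [1.0, -1.0]})
    ext = pd.DataFrame(
        {"gene": ["Tcp1", "Bex1"], "log2fc": [0.5, -0.2], "fdr": [0.01, 0.2]}
    )
    empty = cross_dataset_compare(
        human, ext, pd.DataFrame({"human": [], "external": []})
    )
    assert empty.empty
    omap = pd.DataFrame({"human": ["TCP1", "BEX1"], "external": ["Tcp1", "Bex1"]})
    rep = cross_dataset_compare(human, ext, omap)
    assert rep["concordant"].all()
    assert rep["external_significant"].tolist() == [True, False]


def test_cross_dataset_synthetic_twogroup_discordance():
    """A module planted *down* in aggregate-bearing cells reads as
    discordant with a human list claiming the module is up in severe."""
    from hemidiff.synthetic import simulate_twogroup
    from scipy import stats as sps

    counts, meta = simulate_twogroup(40, module_lfc=-1.5, seed=21)
    agg = (meta["group"] == "aggregate").to_numpy()
    logc = np.log2(counts.counts + 0.5)
    lfc = logc[:, agg].mean(axis=1) - logc[:, ~agg].mean(axis=1)
    t, p = sps.ttest_ind(logc[:, agg], logc[:, ~agg], axis=1)
    ext = pd.DataFrame(
        {
            "gene": counts.gene_ids,
            "log2fc": lfc,
            "fdr": np.minimum(p * len(p), 1.0),  # Bonferroni is fine here
        }
    )
    module = [g for g in counts.gene_ids if g.startswith("MODP")]
    human = pd.DataFrame({"gene_id": module, "direction": 1.0})
    omap = pd.DataFrame({"human": module, "external": module})
    rep = cross_dataset_compare(human, ext, omap)
    assert len(rep) == len(module)
    assert (~rep["concordant"]).all()
    assert rep["external_significant"].all()
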