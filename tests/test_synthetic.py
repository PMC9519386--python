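import math

import numpy as np
import pytest

from caseinlab import bioactivity as ba
from caseinlab import synthetic as syn
from caseinlab.phylo import bipartitions, nj_tree, p_distance_matrix
from caseinlab.align import stack_alignment
from caseinlab.seqio import ALPHABET, ProteinSequence


def test_composition_target_validation():
    with pytest.raises(ValueError):
        syn.CompositionTarget({"A": 1.0})
    with pytest.raises(ValueError):
        syn.CompositionTarget({aa: 0.06 for aa in ALPHABET})  # sums to 1.2
    uni = syn.CompositionTarget.uniform()
    assert sum(uni.fractions.values()) == pytest.approx(1.0)


def test_group_fraction_composition_hits_targets():
    comp = syn.CompositionTarget.from_group_fractions(0.45, 0.12)
    hydro = sum(comp.fractions[aa] for aa in syn.HYDROPHOBIC)
    basic = sum(comp.fractions[aa] for aa in syn.BASIC)
    assert hydro == pytest.approx(0.45)
    assert basic == pytest.approx(0.12)


def test_sample_degenerate_composition():
    comp = syn.CompositionTarget({aa: (1.0 if aa == "A" else 0.0) for aa in ALPHABET})
    assert syn.sample_sequence(comp, 5, seed=0) == "AAAAA"


def test_sample_deterministic_under_seed():
    comp = syn.CompositionTarget.uniform()
    assert syn.sample_sequence(comp, 200, seed=9) == syn.sample_sequence(comp, 200, seed=9)
    assert syn.sample_sequence(comp, 200, seed=9) != syn.sample_sequence(comp, 200, seed=10)


def test_sample_rejects_bad_length():
    with pytest.raises(ValueError):
        syn.sample_sequence(syn.CompositionTarget.uniform(), 0, seed=0)


def test_empirical_composition_converges():
    """Law of large numbers: at length 1e5 every residue fraction is within
    +/-0.01 of its target (direct counting oracle)."""
    seq = syn.sample_sequence(syn.CompositionTarget.uniform(), 100_000, seed=1)
    for aa in ALPHABET:
        assert seq.count(aa) / 100_000 == pytest.approx(0.05, abs=0.01)


def test_plant_stretch_overwrites_exactly_the_interval():
    out = syn.plant_stretch("D" * 40, "R" * 12, 10, 12, seed=0)
    assert out[:10] == "D" * 10
    assert out[10:22] == "R" * 12
    assert out[22:] == "D" * 18


def test_plant_stretch_identity_and_bounds():
    assert syn.plant_stretch("DDDD", "", 2, 0) == "DDDD"
    with pytest.raises(ValueError):
        syn.plant_stretch("DDDD", "RRR", 2, 3)


def test_plant_stretch_preserves_multiset():
    out = syn.plant_stretch("D" * 30, "RKWRKWRKW", 5, 9, seed=4)
    assert sorted(out[5:14]) == sorted("RKWRKWRKW")


def test_planted_low_pv_segment_recovered_by_scanner():
    """Ground-truth property: a long-enough low-PV segment in a high-PV
    background is called exactly once, within window-1 of its true bounds."""
    params = ba.PropensityParams()
    margin = params.window - 1
    length = params.min_stretch + margin  # guarantees a callable run
    for seed in range(5):
        seq = syn.plant_stretch("E" * 80, "R" * length, 20, length, seed=seed)
        stretches = ba.scan_sequence(seq, params).stretches
        assert len(stretches) == 1
        s, e = stretches[0]
        assert s >= 20 - margin and e <= 20 + length + margin
        assert s < 20 + length and e > 20  # overlaps the planted interval


def test_evolve_zero_branches_copies_root():
    leaves = syn.evolve_on_tree("ACDE" * 10, "(x:0.0,(y:0.0,z:0.0):0.0);", seed=3)
    assert set(leaves) == {"x", "y", "z"}
    assert all(v == "ACDE" * 10 for v in leaves.values())


def test_evolve_deterministic_under_seed():
    tree = "(a:0.1,b:0.2,c:0.3,d:0.4);"
    root = syn.sample_sequence(syn.CompositionTarget.uniform(), 300, seed=0)
    l1 = syn.evolve_on_tree(root, tree, seed=7)
    l2 = syn.evolve_on_tree(root, tree, seed=7)
    assert l1 == l2
    assert l1 != syn.evolve_on_tree(root, tree, seed=8)


def test_evolve_requires_branch_lengths():
    with pytest.raises(ValueError):
        syn.evolve_on_tree("ACDE", "(x,y);", seed=0)


def test_evolve_pairwise_distance_matches_expectation():
    """Two leaves at branch length 0.01 from the root: the chance two sites
    stay equal is exp(-0.02) + (1-exp(-0.01))^2/19; the mean p-distance over
    200 length-10,000 replicates must match within +/-0.003."""
    a = math.exp(-0.01)
    expected_p = 1.0 - (a * a + (1.0 - a) ** 2 / 19.0)
    root = syn.sample_sequence(syn.CompositionTarget.uniform(), 10_000, seed=2)
    diffs = []
    for seed in range(200):
        leaves = syn.evolve_on_tree(root, "(u:0.01,v:0.01);", seed=seed)
        u, v = leaves["u"], leaves["v"]
        diffs.append(sum(x != y for x, y in zip(u, v)) / len(u))
    assert np.mean(diffs) == pytest.approx(expected_p, abs=0.003)


def test_make_panel_covers_all_labels(panel_spec, panel):
    assert set(panel) == set(panel_spec.species_labels)
    for sp in panel:
        assert set(panel[sp]) == set(panel_spec.class_labels)
        for cls, seq in panel[sp].items():
            assert (seq.species, seq.casein_class) == (sp, cls)
            lo, hi = panel_spec.length_range
            assert lo <= len(seq) <= hi


def test_make_panel_deterministic(panel_spec, panel):
    again = syn.make_panel(panel_spec)
    for sp in panel:
        for cls in panel[sp]:
            assert again[sp][cls] == panel[sp][cls]


def test_make_panel_class_lengths_shared_within_class(panel):
    # no indels: all species share each class's root length
    for cls in next(iter(panel.values())):
        assert len({len(panel[sp][cls]) for sp in panel}) == 1


def test_nj_on_panel_recovers_generating_cherries(panel_spec, panel):
    from caseinlab.seqio import concat_by_species

    combined = concat_by_species(panel)
    seqs = [combined[sp] for sp in panel_spec.species_labels]
    aln = stack_alignment(
        [ProteinSequence(id=s.species, residues=s.residues) for s in seqs]
    )
    splits = bipartitions(nj_tree(p_distance_matrix(aln)))
    everyone = set(panel)

    def has_cherry(pair: set) -> bool:
        return frozenset(pair) in splits or frozenset(everyone - pair) in splits

    assert has_cherry({"sheep", "goat"})
    assert has_cherry({"cattle", "buffalo"})


def test_panel_spec_validation():
    with pytest.raises(ValueError):
        syn.PanelSpec(species_labels=("a", "b"), divergence_tree="(a:0.1,c:0.1);")
    with pytest.raises(ValueError):
        syn.PanelSpec(
            species_labels=("a", "b"),
            divergence_tree="(a:0.1,b:0.1);",
            length_range=(50, 60),
            planted_stretches={"beta": (("R" * 20, 45, 20),)},
        )


def test_ground_truth_table_rows(panel_spec):
    rows = syn.panel_ground_truth_rows(panel_spec)
    assert len(rows) == len(panel_spec.species_labels) * len(panel_spec.class_labels)
    assert all("tree_newick" in r for r in rows)
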