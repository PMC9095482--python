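"""Density features -> candidate patterns: enumeration, ranking."""

import random

import pytest

from filamentid import (
    BackgroundModel,
    ConstraintSet,
    DensityFeature,
    NoFeasiblePatternError,
    build_patterns,
    parse_pattern,
    scan_fasta,
    scan_sequence,
)
from filamentid.constraints import RankedPattern, load_constraints, rank_patterns
from filamentid.scanner import SequenceRecord
from filamentid.stats import information_bits, window_match_probability

from conftest import COMBINED_PATTERN_TEXT


def glycan_features(offsets, uncertainties=None):
    uncertainties = uncertainties or [0] * len(offsets)
    return tuple(
        DensityFeature(rung_offset=o, feature_class="glycosylated-asn", offset_uncertainty=u)
        for o, u in zip(offsets, uncertainties)
    )


class TestBuildPatterns:
    def test_four_glycan_offsets_give_the_combined_pattern(self):
        cs = ConstraintSet(glycan_features([0, 6, 19, 38]), name="glycans")
        (pattern,) = build_patterns(cs)
        assert pattern.canonical() == COMBINED_PATTERN_TEXT
        assert pattern.span == 38 + 3  # last offset + sequon footprint

    def test_uncertain_spacer_enumerates_three_patterns(self):
        cs = ConstraintSet(glycan_features([0, 6], uncertainties=[0, 1]))
        patterns = sorted(p.canonical() for p in build_patterns(cs))
        assert patterns == [
            "N-x-[ST]-x(2)-N-x-[ST]",
            "N-x-[ST]-x(3)-N-x-[ST]",
            "N-x-[ST]-x(4)-N-x-[ST]",
        ]

    def test_disulfide_pair_locates_cysteines_on_tmem106b(self, tmem106b):
        cs = ConstraintSet(
            (
                DensityFeature(0, feature_class="disulfide-cys"),
                DensityFeature(39, feature_class="disulfide-cys"),
            ),
            name="cys-pair",
        )
        (pattern,) = build_patterns(cs)
        assert pattern.canonical() == "C-x(38)-C"
        hits = scan_sequence(pattern, tmem106b, region=(120, 254))
        assert [h.anchor_positions for h in hits] == [(214, 253)]

    def test_adjacent_sequons_have_no_spacer(self):
        cs = ConstraintSet(glycan_features([0, 3]))
        (pattern,) = build_patterns(cs)
        assert pattern.canonical() == "N-x-[ST]-N-x-[ST]"

    def test_infeasible_combinations_dropped_and_all_dropped_is_error(self):
        # offsets 0 and 2: second anchor would sit inside the first sequon
        cs = ConstraintSet(glycan_features([0, 2]))
        with pytest.raises(NoFeasiblePatternError):
            build_patterns(cs)

    def test_expansion_bound_enforced(self):
        cs = ConstraintSet(glycan_features([0, 50], uncertainties=[3, 3]))
        with pytest.raises(ValueError, match="bound"):
            build_patterns(cs, max_patterns=10)

    def test_strict_sequon_forbids_proline_at_x(self):
        cs = ConstraintSet(glycan_features([0, 6]))
        (pattern,) = build_patterns(cs, strict_sequon=True)
        rec = SequenceRecord(id="s", residues="NPSAAANPS")
        assert scan_sequence(pattern, rec) == []
        rec_ok = SequenceRecord(id="s", residues="NASAAANAS")
        assert len(scan_sequence(pattern, rec_ok)) == 1

    def test_self_consistency_generated_pattern_hits_planted_features(self):
        rng = random.Random(99)
        for _ in range(25):
            k = rng.randint(2, 4)
            offsets = [0]
            for _ in range(k - 1):
                offsets.append(offsets[-1] + rng.randint(3, 12))
            cs = ConstraintSet(glycan_features(offsets))
            (pattern,) = build_patterns(cs)
            residues = ["A"] * (offsets[-1] + 3)
            for o in offsets:
                residues[o], residues[o + 2] = "N", "T"
            rec = SequenceRecord(id="planted", residues="".join(residues))
            assert len(scan_sequence(pattern, rec)) >= 1

    def test_single_feature_is_rejected(self):
        with pytest.raises(ValueError):
            ConstraintSet(glycan_features([0]))


class TestRankPatterns:
    def test_more_constrained_pattern_ranks_first(self, tmem106b):
        combined = parse_pattern(COMBINED_PATTERN_TEXT)
        sub = parse_pattern("N-x-[ST]-x(3)-N-x-[ST]")
        ranked = rank_patterns([sub, combined], [tmem106b], BackgroundModel.uniform())
        assert ranked[0].pattern == combined

    def test_single_pattern_in_single_out(self, tmem106b):
        combined = parse_pattern(COMBINED_PATTERN_TEXT)
        ranked = rank_patterns([combined], [tmem106b], BackgroundModel.uniform())
        assert len(ranked) == 1 and ranked[0].pattern == combined

    def test_ranking_matches_recomputed_keys_on_decoys(self):
        from filamentid import DecoySpec, ImplantSpec, LengthDistribution, generate_proteome

        partial_target = parse_pattern("N-x-[ST]-x(3)-N-x-[ST]")
        proteome = generate_proteome(
            DecoySpec(
                seed=5,
                n_sequences=60,
                lengths=LengthDistribution(length=200),
                implants=(
                    ImplantSpec(partial_target, n_copies=1, mode="partial", degrade_elements=(0,)),
                ),
            )
        ).records
        bg = BackgroundModel.uniform()
        candidates = [
            parse_pattern(t)
            for t in ["N-x-[ST]", "N-x-[ST]-x(3)-N-x-[ST]", "[ST]-x-N", "N-x(2)-[ST]"]
        ]
        ranked = rank_patterns(candidates, proteome, bg)
        # exhaustive recomputation of the three ranking keys
        keys = {}
        for p in candidates:
            report = scan_fasta(p, proteome)
            keys[p.canonical()] = (
                window_match_probability(p, bg) * report.n_windows,
                len(report.hits),
                -information_bits(p, bg),
                p.canonical(),
            )
        expected_order = sorted(keys, key=keys.get)
        assert [r.pattern.canonical() for r in ranked] == expected_order


def test_load_constraints_from_yaml(tmp_path):
    config = tmp_path / "c.yaml"
    config.write_text(
        "name: demo\nfeatures:\n"
        "  - {offset: 0, class: glycosylated-asn}\n"
        "  - {offset: 10, class: disulfide-cys, uncertainty: 1}\n"
        "  - {offset: 20, class: generic-residue, residues: WY}\n"
    )
    cs = load_constraints(config)
    assert cs.name == "demo"
    assert [f.rung_offset for f in cs.features] == [0, 10, 20]
    assert cs.features[2].residue_class == frozenset("WY")
    assert cs.expansion_count == 3


def test_packaged_glycan_config_reproduces_the_fingerprint():
    from importlib import resources

    path = resources.files("filamentid.data") / "glycan_constraints.yaml"
    cs = load_constraints(str(path))
    (pattern,) = build_patterns(cs)
    assert pattern.canonical() == COMBINED_PATTERN_TEXT
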