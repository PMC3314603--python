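"""Window grid, MAF scoring, window selection and the design pipeline."""

import random

import pytest

from ldpanel.core import BreedFrequencyTable, SnpRecord, ValidationError
from ldpanel.design import (
    CriterionConfig,
    SelectionConfig,
    apply_backward_compatibility,
    build_window_grid,
    combine_criteria,
    design_panel,
    fill_gaps,
    score_min_maf,
    score_weighted_mean_maf,
    select_in_windows,
    select_x,
    two_round_select,
)


def snp(name, chrom="1", pos=1, tier=None):
    return SnpRecord(name=name, chromosome=chrom, position=pos, tier=tier)


def basic_cfg(**kw):
    kw.setdefault("round1", CriterionConfig(mean_breeds=["B1"], min_breeds=["B1"]))
    kw.setdefault("compat_target", 0)
    return SelectionConfig(**kw)


# ---------------------------------------------------------------------------
# Window grid
# ---------------------------------------------------------------------------

def test_window_grid_tiling_and_terminals():
    grid = build_window_grid({"1": 1_200_000}, 500_000)
    ws = grid.windows("1")
    assert [(w.start, w.end) for w in ws] == [
        (1, 500_000), (500_001, 1_000_000), (1_000_001, 1_200_000)
    ]
    assert [w.terminal for w in ws] == [True, False, True]


@pytest.mark.parametrize("length", [400_000, 500_000])
def test_single_window_chromosome_is_terminal_once(length):
    ws = build_window_grid({"1": length}, 500_000).windows("1")
    assert len(ws) == 1 and ws[0].terminal and ws[0].end == length


def test_window_grid_rejects_nonpositive_length():
    with pytest.raises(ValidationError):
        build_window_grid({"1": 0})


def test_window_lookup_beyond_length_rejected():
    grid = build_window_grid({"1": 1_000_000}, 500_000)
    with pytest.raises(ValidationError):
        grid.window_for("1", 2_000_000)
    with pytest.raises(ValidationError):
        grid.window_for("2", 100)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def test_weighted_mean_maf_double_weight():
    t = BreedFrequencyTable.from_mapping(
        {("s", "Holstein"): 0.4, ("s", "Jersey"): 0.2}
    )
    scores = score_weighted_mean_maf(t, ["Holstein", "Jersey"], {"Holstein": 2.0})
    assert scores["s"] == pytest.approx(1.0 / 3.0)


def test_weighted_mean_single_breed_and_missing_entry():
    t = BreedFrequencyTable.from_mapping({("s", "Holstein"): 0.4})
    assert score_weighted_mean_maf(t, ["Holstein"])["s"] == pytest.approx(0.4)
    # Jersey entry missing: score falls back to the Holstein MAF
    assert score_weighted_mean_maf(t, ["Holstein", "Jersey"])["s"] == pytest.approx(0.4)
    with pytest.raises(ValidationError):
        score_weighted_mean_maf(t, [])


def test_min_maf_and_combination():
    t = BreedFrequencyTable.from_mapping(
        {("s", "A"): 0.4, ("s", "B"): 0.2, ("s", "C"): 0.35, ("u", "A"): 0.3}
    )
    assert score_min_maf(t, ["A", "B", "C"])["s"] == pytest.approx(0.2)
    combined = combine_criteria({"s": 0.4, "u": 0.3}, {"s": 0.2})
    assert combined == {"s": pytest.approx(0.3)}  # u lacks criterion B


# ---------------------------------------------------------------------------
# Window selection
# ---------------------------------------------------------------------------

def test_interior_window_argmax_and_terminal_doubling():
    grid = build_window_grid({"1": 1_500_000}, 500_000)
    cfg = basic_cfg()
    cands = [snp("a", pos=600_000), snp("b", pos=700_000), snp("c", pos=800_000)]
    sel = select_in_windows(cands, {"a": 0.3, "b": 0.5, "c": 0.4}, grid, cfg)
    assert sel.names == {"b"}  # interior window keeps the single best
    term = [snp("x", pos=100), snp("y", pos=200), snp("z", pos=300)]
    sel = select_in_windows(term, {"x": 0.1, "y": 0.3, "z": 0.2}, grid, cfg)
    assert sel.names == {"y", "z"}  # terminal window keeps the top two
    reasons = {e.record.name: e.reason for e in sel.entries}
    assert reasons == {"y": "WINDOW_BEST", "z": "TERMINAL_EXTRA"}


def test_select_in_windows_matches_bruteforce_oracle():
    rng = random.Random(5)
    for _ in range(20):
        n_chrom = rng.randint(1, 10)
        lengths = {str(c): rng.randint(1, 6) * 500_000 for c in range(1, n_chrom + 1)}
        grid = build_window_grid(lengths, 500_000)
        cfg = basic_cfg()
        cands, scores = [], {}
        for k in range(rng.randint(10, 2000)):
            chrom = str(rng.randint(1, n_chrom))
            rec = snp(f"s{k}", chrom, rng.randint(1, lengths[chrom]))
            cands.append(rec)
            scores[rec.name] = round(rng.random(), 3)
        got = select_in_windows(cands, scores, grid, cfg).names
        # oracle: exhaustive sort per window
        expected = set()
        by_window = {}
        for rec in cands:
            w = (rec.chromosome, (rec.position - 1) // 500_000)
            by_window.setdefault(w, []).append(rec)
        for (chrom, widx), recs in by_window.items():
            terminal = widx == 0 or widx == len(grid.windows(chrom)) - 1
            k = cfg.terminal_picks if terminal else cfg.picks_per_window
            ranked = sorted(recs, key=lambda r: (-scores[r.name], r.position, r.name))
            expected |= {r.name for r in ranked[:k]}
        assert got == expected


def test_candidate_off_grid_rejected():
    grid = build_window_grid({"1": 1_000_000})
    with pytest.raises(ValidationError):
        select_in_windows([snp("a", "2", 5)], {"a": 0.1}, grid, basic_cfg())


# ---------------------------------------------------------------------------
# Two-round selection
# ---------------------------------------------------------------------------

def test_round2_inverts_round1_ranking():
    """Round 2 picks its own winners from the round-1 survivor pool."""
    grid = build_window_grid({"1": 500_000, "2": 500_000})
    cfg = SelectionConfig(
        round1=CriterionConfig(mean_breeds=["E"], min_breeds=["E"]),
        round2=CriterionConfig(mean_breeds=["N"], min_breeds=["N"]),
        terminal_picks=2,
        compat_target=0,
    )
    entries = {}
    for chrom in ("1", "2"):
        for k, (e_maf, n_maf) in enumerate([(0.5, 0.05), (0.4, 0.1), (0.3, 0.5)]):
            name = f"c{chrom}_{k}"
            entries[(name, "E")] = e_maf
            entries[(name, "N")] = n_maf
    t = BreedFrequencyTable.from_mapping(entries)
    cands = [snp(f"c{c}_{k}", c, 1000 * (k + 1)) for c in ("1", "2") for k in range(3)]
    sel = two_round_select(cands, t, grid, cfg)
    # round 1 keeps the two highest-E candidates (k=0,1); round 2 ranks them
    # by N, so k=1 beats k=0 — the k=2 candidate is gone despite top N score
    assert sel.names == {"c1_0", "c1_1", "c2_0", "c2_1"}
    for chrom in ("1", "2"):
        best = max((f"c{chrom}_0", f"c{chrom}_1"), key=lambda n: entries[(n, "N")])
        assert sel.get(best).reason == "WINDOW_BEST"


def test_round2_noop_when_pool_already_at_size():
    grid = build_window_grid({"1": 400_000})
    cfg = SelectionConfig(
        round1=CriterionConfig(mean_breeds=["E"], min_breeds=["E"]),
        round2=CriterionConfig(mean_breeds=["N"], min_breeds=["N"]),
        compat_target=0,
    )
    t = BreedFrequencyTable.from_mapping(
        {("a", "E"): 0.4, ("a", "N"): 0.1, ("b", "E"): 0.3, ("b", "N"): 0.5}
    )
    sel = two_round_select([snp("a", pos=10), snp("b", pos=20)], t, grid, cfg)
    assert len(sel) == 2  # terminal window keeps both; round 2 cannot thin it


def test_two_round_empty_input():
    grid = build_window_grid({"1": 500_000})
    assert len(two_round_select([], BreedFrequencyTable(), grid, basic_cfg())) == 0


# ---------------------------------------------------------------------------
# Backward compatibility
# ---------------------------------------------------------------------------

def _selection_of(*records):
    from ldpanel.design import PanelDesign, PanelEntry

    return PanelDesign(
        [PanelEntry(record=r, reason="WINDOW_BEST", window=(r.chromosome, 1))
         for r in records]
    )


def test_compat_swap_performed_within_radius():
    sel = _selection_of(snp("orig", pos=250_000))
    out = apply_backward_compatibility(
        sel, [snp("legacy", pos=260_000)], max_shift=100_000, target=1
    )
    assert out.names == {"legacy"}
    assert out.get("legacy").reason == "COMPAT_SWAP"
    assert out.get("legacy").window == ("1", 1)


def test_compat_swap_skipped_beyond_radius():
    sel = _selection_of(snp("orig", pos=250_000))
    out = apply_backward_compatibility(
        sel, [snp("legacy", pos=2_250_000)], max_shift=100_000, target=1
    )
    assert out.names == {"orig"}


def test_compat_identity_when_target_met():
    sel = _selection_of(snp("legacy", pos=250_000))
    out = apply_backward_compatibility(
        sel, [snp("legacy", pos=250_000)], max_shift=100_000, target=1
    )
    assert out.names == {"legacy"}
    assert out.get("legacy").reason == "WINDOW_BEST"


# ---------------------------------------------------------------------------
# Gap filling
# ---------------------------------------------------------------------------

def test_fill_gap_with_midpoint_candidate():
    sel = _selection_of(snp("a", pos=100_000), snp("b", pos=1_600_000))
    out = fill_gaps(sel, [snp("mid", pos=800_000)], max_gap=1_000_000)
    assert out.names == {"a", "b", "mid"}
    assert out.get("mid").reason == "GAP_FILL"
    positions = [e.record.position for e in out.entries]
    assert max(b - a for a, b in zip(positions, positions[1:])) <= 1_000_000


def test_unfillable_gap_left_in_place():
    sel = _selection_of(snp("a", pos=100_000), snp("b", pos=1_600_000))
    out = fill_gaps(sel, [snp("far", "2", 800_000)], max_gap=1_000_000)
    assert out.names == {"a", "b"}


def test_fill_gaps_identity_when_all_gaps_small():
    sel = _selection_of(snp("a", pos=100_000), snp("b", pos=900_000))
    assert fill_gaps(sel, [snp("mid", pos=500_000)], 1_000_000).names == {"a", "b"}


def test_no_fillable_gap_remains_after_fill():
    rng = random.Random(11)
    sel = _selection_of(
        *[snp(f"s{k}", pos=p) for k, p in enumerate(sorted(rng.sample(range(1, 20_000_000), 12)))]
    )
    pool = [snp(f"p{k}", pos=rng.randint(1, 20_000_000)) for k in range(40)]
    out = fill_gaps(sel, pool, max_gap=1_000_000)
    recs = [e.record for e in out.entries]
    pool_left = {r.name for r in pool} - out.names
    for a, b in zip(recs, recs[1:]):
        gap = b.position - a.position
        if gap > 1_000_000:
            inside = [
                p for p in pool
                if p.name in pool_left and a.position < p.position < b.position
            ]
            assert inside == []


# ---------------------------------------------------------------------------
# X selection and full pipeline
# ---------------------------------------------------------------------------

def test_x_tier_priority_beats_score():
    grid = build_window_grid({"X": 500_000})
    cfg = basic_cfg()
    t = BreedFrequencyTable.from_mapping({("low3k", "B1"): 0.2, ("hi50", "B1"): 0.45})
    tiers = [[snp("low3k", "X", 100, "BOVINE3K")], [snp("hi50", "X", 200, "BOVINESNP50")]]
    sel = select_x(tiers, t, grid, cfg)
    assert "low3k" in sel.names and "hi50" not in sel.names


def test_x_tier_fallthrough_when_higher_tier_empty():
    grid = build_window_grid({"X": 500_000})
    t = BreedFrequencyTable.from_mapping({("hd", "B1"): 0.3})
    sel = select_x([[], [], [snp("hd", "X", 100, "BOVINEHD")]], t, grid, basic_cfg())
    assert sel.names == {"hd"}


def _pipeline_inputs():
    lengths = {"1": 1_500_000, "2": 1_500_000, "X": 1_000_000}
    cands, entries = [], {}
    rng = random.Random(3)
    for chrom in ("1", "2"):
        for k in range(30):
            name = f"a{chrom}_{k}"
            cands.append(snp(name, chrom, rng.randint(1, lengths[chrom])))
            entries[(name, "B1")] = round(rng.uniform(0.05, 0.5), 3)
    x_cands = []
    for k in range(10):
        name = f"x_{k}"
        tier = ("BOVINE3K", "BOVINESNP50", "BOVINEHD")[k % 3]
        x_cands.append(snp(name, "X", rng.randint(1, lengths["X"]), tier))
        entries[(name, "B1")] = round(rng.uniform(0.05, 0.5), 3)
    cfg = SelectionConfig(
        round1=CriterionConfig(mean_breeds=["B1"], min_breeds=["B1"]),
        chrom_lengths=lengths,
        compat_target=0,
    )
    return cfg, cands + x_cands, BreedFrequencyTable.from_mapping(entries)


def test_design_panel_window_occupancy():
    cfg, cands, table = _pipeline_inputs()
    panel = design_panel(cfg, cands, table)
    from collections import Counter

    per_window = Counter(
        e.window for e in panel.entries
        if e.window and e.record.chromosome in ("1", "2")
    )
    for (chrom, widx), count in per_window.items():
        assert count == (2 if widx in (1, 3) else 1)


def test_design_panel_mandatory_dedup_and_fixed_lists():
    cfg, cands, table = _pipeline_inputs()
    base = design_panel(cfg, cands, table)
    already = base.entries[0].record
    y = [snp("y1", "Y", 100)]
    mt = [snp("mt1", "MT", 100)]
    panel = design_panel(cfg, cands, table, mandatory=[already], y_fixed=y, mt_fixed=mt)
    assert panel.get(already.name).reason == "WINDOW_BEST"  # no duplicate entry
    assert panel.get("y1").reason == "Y_FIXED"
    assert panel.get("mt1").reason == "MT_FIXED"
    # without extras the panel is autosomal + X only
    assert {e.record.chromosome for e in base.entries} <= {"1", "2", "X"}


def test_design_panel_permutation_invariant():
    cfg, cands, table = _pipeline_inputs()
    panel1 = design_panel(cfg, cands, table)
    shuffled = list(cands)
    random.Random(99).shuffle(shuffled)
    panel2 = design_panel(cfg, shuffled, table)
    assert [(e.record.name, e.reason, e.window) for e in panel1.entries] == [
        (e.record.name, e.reason, e.window) for e in panel2.entries
    ]


def test_design_output_sorted_and_duplicate_free():
    cfg, cands, table = _pipeline_inputs()
    panel = design_panel(cfg, cands, table)
    keys = [e.record.sort_key for e in panel.entries]
    assert keys == sorted(keys)
    names = [e.record.name for e in panel.entries]
    assert len(names) == len(set(names))


def test_selected_score_dominates_unselected_in_window():
    cfg, cands, table = _pipeline_inputs()
    panel = design_panel(cfg, cands, table)
    from ldpanel.design import criterion_scores

    _, _, combined = criterion_scores(table, cfg.round1)
    grid = build_window_grid(cfg.chrom_lengths, cfg.window_size)
    for e in panel.entries:
        if e.reason not in ("WINDOW_BEST", "TERMINAL_EXTRA") or e.window is None:
            continue
        chrom, widx = e.window
        rivals = [
            c for c in cands
            if c.chromosome == chrom and c.name not in panel.names
            and grid.window_for(chrom, c.position).index == widx
        ]
        for rival in rivals:
            assert combined[e.record.name] >= combined[rival.name]
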