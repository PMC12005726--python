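"""Read-pair parsing, count-matrix construction, and representation QC."""

import numpy as np
import pandas as pd
import pytest

import combiscreen as cs
from combiscreen.counting import (
    AnchorConfig,
    count_pairs,
    find_anchor,
    pair_index,
    parse_read_pair,
    reverse_complement,
)

CFG = AnchorConfig(fwd_anchor="ACGTACGTAA", rev_anchor="TTGGCCAATT", spacer_len=20)


def _reads_for(design, a, b, cfg=CFG, read_len=60):
    sp = {s.id: s.spacer for s in design.sgrnas}
    filler = "G" * read_len
    fwd = (cfg.fwd_anchor + sp[a] + filler)[:read_len]
    rev = reverse_complement((cfg.rev_anchor + sp[b] + filler)[:read_len])
    return fwd, rev


def test_parse_read_pair_matches_constructed_reads(small_design):
    ids = [s.id for s in small_design.sgrnas]
    a, b = ids[0], ids[-1]
    fwd, rev = _reads_for(small_design, a, b)
    res = parse_read_pair(fwd, rev, CFG, small_design)
    assert res.status == "ok" and res.pair == (a, b)


def test_parse_read_pair_typed_misses(small_design):
    ids = [s.id for s in small_design.sgrnas]
    fwd, rev = _reads_for(small_design, ids[0], ids[1])
    # corrupt the forward anchor beyond the mismatch budget
    bad = "TTTTTTTTTT" + fwd[10:]
    assert parse_read_pair(bad, rev, CFG, small_design).status == "anchor_not_found"
    # replace the spacer with a sequence absent from the library
    unknown = CFG.fwd_anchor + "A" * 20 + "G" * 30
    assert parse_read_pair(unknown, rev, CFG, small_design).status == "spacer_unknown"


def test_parser_agrees_with_bruteforce_oracle(small_design):
    """Leftmost-anchor-within-budget scan + exact spacer lookup, 10,000 reads."""
    rng = np.random.default_rng(99)
    spacers = list(small_design.spacer_to_id)
    bases = np.array(list("ACGT"))

    def oracle_find(seq, anchor, mm, spl):
        last = len(seq) - len(anchor) - spl
        for off in range(last + 1):
            d = sum(1 for x, y in zip(seq[off : off + len(anchor)], anchor) if x != y)
            if d <= mm:
                return off
        return -1

    def oracle(fwd, rev):
        rev = reverse_complement(rev)
        p1 = oracle_find(fwd, CFG.fwd_anchor, CFG.max_mismatches, CFG.spacer_len)
        if p1 < 0:
            return ("anchor_not_found", None)
        p2 = oracle_find(rev, CFG.rev_anchor, CFG.max_mismatches, CFG.spacer_len)
        if p2 < 0:
            return ("anchor_not_found", None)
        s1 = fwd[p1 + len(CFG.fwd_anchor) :][: CFG.spacer_len]
        s2 = rev[p2 + len(CFG.rev_anchor) :][: CFG.spacer_len]
        i1 = small_design.spacer_to_id.get(s1)
        i2 = small_design.spacer_to_id.get(s2)
        if i1 is None or i2 is None:
            return ("spacer_unknown", None)
        return ("ok", (i1, i2))

    def random_read():
        kind = rng.random()
        if kind < 0.6:  # well-formed read with sprinkled errors
            sp = spacers[rng.integers(len(spacers))]
            seq = list(CFG.fwd_anchor + sp + "".join(rng.choice(bases, 30)))
            for pos in np.nonzero(rng.random(len(seq)) < 0.03)[0]:
                seq[pos] = bases[rng.integers(4)]
            return "".join(seq)
        return "".join(rng.choice(bases, 60))  # junk

    for _ in range(5000):  # 5000 read pairs = 10,000 reads
        fwd = random_read()
        rev = reverse_complement(random_read())
        got = parse_read_pair(fwd, rev, CFG, small_design)
        assert (got.status, got.pair) == oracle(fwd, rev)


def test_count_pairs_empty_fastq(tmp_path, small_design):
    f1, f2 = tmp_path / "e_1.fastq", tmp_path / "e_2.fastq"
    f1.write_text("")
    f2.write_text("")
    col, stats = count_pairs(f1, f2, CFG, small_design)
    assert col.sum() == 0 and stats["total_reads"] == 0
    assert len(col) == len(small_design) ** 2  # full universe with zeros


def test_count_pairs_duplicate_read_increments_twice(tmp_path, small_design):
    ids = [s.id for s in small_design.sgrnas]
    fwd, rev = _reads_for(small_design, ids[0], ids[1])
    f1, f2 = tmp_path / "d_1.fastq", tmp_path / "d_2.fastq"
    f1.write_text(f"@r1\n{fwd}\n+\n{'I' * len(fwd)}\n@r2\n{fwd}\n+\n{'I' * len(fwd)}\n")
    f2.write_text(f"@r1\n{rev}\n+\n{'I' * len(rev)}\n@r2\n{rev}\n+\n{'I' * len(rev)}\n")
    col, stats = count_pairs(f1, f2, CFG, small_design)
    assert col[(ids[0], ids[1])] == 2
    assert stats["matched"] == 2


def test_count_pairs_desynchronized_mates(tmp_path, small_design):
    ids = [s.id for s in small_design.sgrnas]
    fwd, rev = _reads_for(small_design, ids[0], ids[1])
    f1, f2 = tmp_path / "s_1.fastq", tmp_path / "s_2.fastq"
    f1.write_text(f"@r1\n{fwd}\n+\n{'I' * len(fwd)}\n@r2\n{fwd}\n+\n{'I' * len(fwd)}\n")
    f2.write_text(f"@r1\n{rev}\n+\n{'I' * len(rev)}\n")
    with pytest.raises(cs.InputError, match="desynchronized"):
        count_pairs(f1, f2, CFG, small_design)


def test_matched_plus_unmatched_equals_total(tmp_path, small_design):
    counts = pd.Series(0, index=pair_index(small_design))
    rng = np.random.default_rng(3)
    pairs = counts.index.to_list()
    for k in rng.choice(len(pairs), 40):
        counts.iloc[k] += 1
    f1, f2 = tmp_path / "m_1.fastq", tmp_path / "m_2.fastq"
    cs.simulate_fastq(counts, small_design, CFG, f1, f2, error_rate=0.1, seed=5)
    col, stats = count_pairs(f1, f2, CFG, small_design)
    assert stats["matched"] + stats["anchor_not_found"] + stats["spacer_unknown"] == stats["total_reads"]
    assert stats["total_reads"] == 40


def test_simulated_counts_match_multinomial_expectation(tmp_path, small_design):
    """Counts from simulator-emitted FASTQ sit within 4σ of the multinomial law."""
    rng = np.random.default_rng(17)
    idx = pair_index(small_design)
    p = rng.dirichlet(np.ones(len(idx)) * 5)
    n = 20_000
    drawn = pd.Series(rng.multinomial(n, p), index=idx)
    f1, f2 = tmp_path / "mn_1.fastq", tmp_path / "mn_2.fastq"
    cs.simulate_fastq(drawn, small_design, CFG, f1, f2, error_rate=0.0, seed=23)
    col, stats = count_pairs(f1, f2, CFG, small_design)
    assert (col == drawn).all()  # error-free emission is an exact round trip
    sigma = np.sqrt(n * p * (1 - p))
    assert (np.abs(col.to_numpy() - n * p) <= 4 * sigma + 1).all()


def test_rpm_normalize():
    df = pd.DataFrame({"s1": [3, 1], "s2": [10, 0]})
    rpm = cs.rpm_normalize(df)
    assert rpm["s1"].tolist() == [750_000.0, 250_000.0]
    assert np.allclose(rpm.sum(axis=0), 1e6)
    with pytest.raises(cs.InputError, match="zero-depth"):
        cs.rpm_normalize(pd.DataFrame({"s1": [0, 0]}))


def test_representation_qc_uniform_and_zero():
    # >= 3 guides per gene so every gene pair can reach the 6-pair minimum
    design = cs.make_design(n_genes=3, n_sgrna_per_gene=3, n_controls=3, seed=2)
    idx = pair_index(design)
    uniform = pd.Series(10, index=idx)  # depth 10× library size
    qc = cs.representation_qc(uniform, design)
    assert qc.fraction == 1.0
    zero = pd.Series(0, index=idx)
    qc0 = cs.representation_qc(zero, design)
    assert qc0.fraction == 0.0
    assert qc0.n_total == len(cs.enumerate_gene_pairs(design))


def test_representation_qc_scale_invariance(sim_screen):
    """Duplicating every read changes neither RPM nor representation QC."""
    matrix, truth = sim_screen
    col = matrix.counts["D0_R1"]
    qc1 = cs.representation_qc(col, truth.design)
    qc2 = cs.representation_qc(col * 2, truth.design)
    assert qc1.n_pass == qc2.n_pass
    assert (qc1.per_gene_pair == qc2.per_gene_pair).all()


def test_find_anchor_prefers_leftmost_within_budget():
    #        0123456789
    seq = "TTACGTACGTAAGGGG" + "A" * 20
    assert find_anchor(seq, "ACGTACGTAA", 1, 20) == 2
    assert find_anchor("GG" + "A" * 10, "ACGTACGTAA", 0, 20) == -1  # no room for spacer
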