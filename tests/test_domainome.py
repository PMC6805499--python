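import pytest
from hypothesis import given, settings, strategies as st

from anaerodesign import (
    ConfigurationError,
    GenomeDomainSet,
    categorize_domains,
    core_domains,
    exclusive_core,
    load_domain_annotations,
)
from anaerodesign.domainome import (
    DEFAULT_CATEGORY_MAP,
    presence_absence_matrix,
    shortlist_report,
)
from anaerodesign.oracles import brute_force_exclusive_core

IPS_COLUMNS = [
    "prot1", "md5", "500", "Pfam", "PF00871", "Acetate kinase", "1", "400",
    "1e-50", "T", "01-01-2015", "IPR000890", "Acetokinase family", "GO:0006083",
]


def _ips_line(protein, accession):
    fields = list(IPS_COLUMNS)
    fields[0] = protein
    fields[11] = accession
    return "\t".join(fields)


def test_interproscan_reader_deduplicates_and_skips_unmapped(tmp_path):
    path = tmp_path / "genome.tsv"
    path.write_text(
        "\n".join(
            [
                _ips_line("p1", "IPR000890"),
                _ips_line("p2", "IPR000890"),
                _ips_line("p3", "IPR000890"),
                _ips_line("p4", "-"),
                "\t".join(IPS_COLUMNS[:11]),  # signature row without IPR column
            ]
        )
        + "\n"
    )
    genome = load_domain_annotations(path, dialect="interproscan_tsv", group="anaerobe")
    assert genome.domains == {"IPR000890"}
    assert genome.gene_count == 5


def test_interproscan_reader_strict_mode_flags_short_rows(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("only\tthree\tcolumns\n")
    load_domain_annotations(path, dialect="interproscan_tsv")  # lenient: skip
    with pytest.raises(ConfigurationError, match="bad.tsv:1"):
        load_domain_annotations(path, dialect="interproscan_tsv", strict=True)


def test_simple_tsv_reader_counts_distinct_domains(tmp_path):
    path = tmp_path / "g.tsv"
    path.write_text(
        "genome_id\tgene_id\tdomain_id\n"
        "g1\tgene1\tIPR000001\n"
        "g1\tgene2\tIPR000002\n"
        "g1\tgene3\tIPR000003\n"
        "g1\tgene4\tIPR000004\n"
        "g1\tgene5\tIPR000001\n"
    )
    genome = load_domain_annotations(path, dialect="simple_tsv", group="aerobe")
    assert genome.genome_id == "g1"
    assert len(genome.domains) == 4
    assert genome.gene_count == 5


def _genome(gid, group, domains):
    return GenomeDomainSet(genome_id=gid, group=group, domains=set(domains))


def test_core_domains_identity_and_disjoint():
    a = _genome("a", "anaerobe", {"IPR1", "IPR2"})
    b = _genome("b", "anaerobe", {"IPR3"})
    assert core_domains([a]) == a.domains
    assert core_domains([a, b]) == set()
    with pytest.raises(ConfigurationError):
        core_domains([])


def test_exclusive_core_self_subtraction():
    panel = [_genome(f"g{i}", "anaerobe", {"IPR1", "IPR2"}) for i in range(3)]
    assert exclusive_core(panel, panel) == set()


def test_categorize_empty_default_map_and_unmapped():
    empty = categorize_domains([])
    assert empty.total == 0 and all(v == 0 for v in empty.counts.values())
    named = categorize_domains(["IPR000890", "IPR012833", "IPR012840", "IPR003538"])
    assert named.assignments["IPR000890"] == "atp_generation"
    assert named.assignments["IPR012833"] == "atp_generation"
    assert named.assignments["IPR012840"] == "atp_generation"
    assert named.assignments["IPR003538"] == "other"
    partial = categorize_domains(["IPR1", "IPR2", "IPR000890"], {"IPR1": "other"})
    assert partial.counts["unknown_function"] >= 1
    assert partial.total == 3
    with pytest.raises(ConfigurationError):
        categorize_domains(["IPR1"], {"IPR1": "mystery"})


def test_counts_always_sum_to_total():
    counts = categorize_domains([f"IPR{i:06d}" for i in range(50)], DEFAULT_CATEGORY_MAP)
    assert sum(counts.counts.values()) == counts.total == 50


@st.composite
def panels(draw):
    universe = [f"IPR{i:06d}" for i in range(30)]
    n_t = draw(st.integers(1, 4))
    n_b = draw(st.integers(1, 4))
    target = [
        _genome(f"t{i}", "anaerobe", draw(st.sets(st.sampled_from(universe), min_size=1, max_size=20)))
        for i in range(n_t)
    ]
    background = [
        _genome(f"b{i}", "aerobe", draw(st.sets(st.sampled_from(universe), min_size=1, max_size=20)))
        for i in range(n_b)
    ]
    extra = _genome("x", "anaerobe", draw(st.sets(st.sampled_from(universe), min_size=1, max_size=20)))
    return target, background, extra


@settings(max_examples=60, derandomize=True, deadline=None)
@given(panels())
def test_exclusive_core_set_containment_and_monotonicity(data):
    target, background, extra = data
    result = exclusive_core(target, background)
    assert result <= core_domains(target)
    for genome in background:
        assert not (result & genome.domains)
    # agrees with the naive double-loop oracle
    sets = {g.genome_id: g.domains for g in target + background + [extra]}
    assert result == brute_force_exclusive_core(
        sets, [g.genome_id for g in target], [g.genome_id for g in background]
    )
    # growing either group can only shrink (or preserve) the exclusive core
    assert exclusive_core(target + [extra], background) <= result
    extra_bg = GenomeDomainSet(genome_id="xb", group="aerobe", domains=extra.domains)
    assert exclusive_core(target, background + [extra_bg]) <= result


def test_presence_absence_matrix_and_report():
    genomes = [
        _genome("a1", "anaerobe", {"IPR000001", "IPR000002"}),
        _genome("b1", "aerobe", {"IPR000002"}),
    ]
    matrix = presence_absence_matrix(genomes)
    assert matrix.loc["a1", "IPR000001"] == 1
    assert matrix.loc["b1", "IPR000001"] == 0
    shortlist = exclusive_core([genomes[0]], [genomes[1]])
    report = shortlist_report(shortlist, genomes, categorize_domains(shortlist))
    assert list(report["accession"]) == ["IPR000001"]
    assert report.loc[0, "a1"] == 1 and report.loc[0, "b1"] == 0
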