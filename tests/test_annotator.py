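"""Annotation engine: lookups, self-annotation, oracle equivalence, bin cache."""

import numpy as np
import pytest
from cyvcf2 import VCF

from varzip import annotate_vcf, parse_config
from varzip.annotator import Annotator, BinCache, lookup
from varzip.archive_io import ArchiveReader, BinData, FieldConfig
from varzip.builder import build_archive
from varzip.errors import ExpressionError
from varzip.filter_expr import parse as parse_filter
from varzip.fixtures import oracle_annotate, render_vcf
from varzip.variant_codec import LongVariantRecord, encode32, placeholder32

MULTIPLIER = 100000  # pop_AF multiplier from the standard test configuration


def read_output(path, aliases):
    out = []
    for rec in VCF(str(path)):
        out.append(
            (
                rec.CHROM,
                rec.POS,
                rec.REF,
                rec.ALT[0] if rec.ALT else None,
                {a: rec.INFO.get(a) for a in aliases},
            )
        )
    return out


class TestLookup:
    configs = [
        FieldConfig("AC", ftype="integer"),
        FieldConfig("AF", multiplier=1000, ftype="float"),
    ]

    def _bin(self):
        # one SNP at offset 5 (sorts first), one 5-base insertion at offset 9
        # represented by a placeholder; columns are row-aligned with var32
        var32 = sorted([encode32(5, "A", "C"), placeholder32(9)])
        assert var32 == [encode32(5, "A", "C"), placeholder32(9)]
        return BinData(
            var32=var32,
            longs=[LongVariantRecord(9, "A", "ACGTA", field_index=1)],
            columns={"AC": [3, 7], "AF": [125, 500]},
        )

    def test_short_variant_found(self):
        r = lookup(self._bin(), 5, "A", "C", self.configs, {})
        assert r.found
        assert r.values["AC"] == 3
        assert r.values["AF"] == 0.125

    def test_long_variant_found_via_supplemental_table(self):
        r = lookup(self._bin(), 9, "A", "ACGTA", self.configs, {})
        assert r.found
        assert r.values["AC"] == 7
        assert r.values["AF"] == 0.5

    def test_absent_variant_gets_missing_values(self):
        r = lookup(self._bin(), 5, "A", "G", self.configs, {})
        assert not r.found
        assert r.values == {"AC": -1, "AF": -1.0}

    def test_float_missing_sentinel_not_rescaled(self):
        data = BinData(
            var32=[encode32(5, "A", "C")], columns={"AC": [1], "AF": [-1]}
        )
        r = lookup(data, 5, "A", "C", self.configs, {})
        assert r.values["AF"] == -1.0  # the sentinel itself, not -1/1000


def test_self_annotation_identity(cohort, tmp_path):
    """Annotating the source VCF with its own archive recovers every value."""
    spec, truth, vcf_path, archive_path, configs = cohort
    out = tmp_path / "self.vcf"
    summary = annotate_vcf(vcf_path, [archive_path], None, out)
    assert summary.variants_read == summary.variants_written == len(truth)

    with ArchiveReader(archive_path) as reader:
        by_cfg = {c.field: c for c in reader.configs}  # carries stored ftypes
    n_checked = 0
    for rec, r in zip(VCF(str(out)), truth):
        assert (rec.CHROM, rec.POS, rec.REF, rec.ALT[0]) == (r.chrom, r.pos, r.ref, r.alt)
        for field, cfg in by_cfg.items():
            got = rec.INFO.get(cfg.alias)
            src = r.info.get(field)
            if cfg.ftype == "string":
                assert str(got) == (src if src is not None else "."), (r, field)
            elif cfg.ftype == "float":
                want = src if src is not None else -1.0
                assert abs(float(got) - want) <= 0.5 / cfg.multiplier + 1e-6, (r, field)
            else:
                assert int(got) == (src if src is not None else -1), (r, field)
            n_checked += 1
    assert n_checked == len(truth) * len(configs)


@pytest.mark.parametrize(
    "expression",
    [
        "pop_AF < 0.01",  # threshold
        "pop_nhomalt / (pop_AN / 2) < 0.005",  # arithmetic ratio
        "pop_AF > 0.2 || pop_AC > 20 || pop_nhomalt > 5",  # OR of thresholds
        "pop_CSQ == 'missense' && pop_AF < 0.5",
        None,
    ],
)
@pytest.mark.parametrize("shuffled", [False, True])
def test_oracle_equivalence(cohort, tmp_path, expression, shuffled):
    """Pipeline output equals the naive hash-map oracle, values and survivors."""
    spec, truth, vcf_path, archive_path, configs = cohort
    with ArchiveReader(archive_path) as r:
        stored_configs = r.configs

    queries = list(truth)
    if shuffled:
        rng = np.random.default_rng(99)
        queries = [queries[i] for i in rng.permutation(len(queries))]
        vcf_path = tmp_path / "shuffled.vcf"
        vcf_path.write_text(render_vcf(spec, queries))

    ast = parse_filter(expression) if expression else None
    annotated, surviving = oracle_annotate(truth, queries, stored_configs, ast)
    expected = [
        (queries[i].chrom, queries[i].pos, queries[i].ref, queries[i].alt, annotated[i])
        for i in surviving
    ]

    out = tmp_path / f"out_{bool(expression)}_{shuffled}.vcf"
    summary = annotate_vcf(vcf_path, [archive_path], expression, out)
    assert summary.variants_written == len(surviving)

    aliases = [c.alias for c in stored_configs]
    got = read_output(out, aliases)
    assert len(got) == len(expected)
    for (chrom, pos, ref, alt, values), (echrom, epos, eref, ealt, evalues) in zip(
        got, expected
    ):
        assert (chrom, pos, ref, alt) == (echrom, epos, eref, ealt)
        for cfg in stored_configs:
            g, e = values[cfg.alias], evalues[cfg.alias]
            if cfg.ftype == "float":
                # output floats pass through VCF single precision once more
                assert abs(float(g) - e) <= abs(e) * 1e-6 + 1e-9, (chrom, pos, cfg.alias)
            elif cfg.ftype == "string":
                assert str(g) == e
            else:
                assert int(g) == e


def test_filter_monotonicity(cohort, tmp_path):
    """Filtered output is exactly the filter-true subset of unfiltered output.

    The filter is evaluated on the exact annotated values (as the engine sees
    them), not on the single-precision floats the VCF text carries.
    """
    _, truth, vcf_path, archive_path, _ = cohort
    expression = "pop_AF < 0.01"
    out_all = tmp_path / "all.vcf"
    out_flt = tmp_path / "flt.vcf"
    annotate_vcf(vcf_path, [archive_path], None, out_all)
    annotate_vcf(vcf_path, [archive_path], expression, out_flt)
    ast = parse_filter(expression)
    from varzip.filter_expr import evaluate

    engine = Annotator([archive_path])
    kept = []
    for rec in VCF(str(out_all)):
        env = engine.annotate_record_values(rec.CHROM, rec.POS, rec.REF, rec.ALT[0])
        if evaluate(ast, env):
            kept.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
    engine.close()
    got = [(rec.CHROM, rec.POS, rec.REF, rec.ALT[0]) for rec in VCF(str(out_flt))]
    assert got == kept


def test_two_archives_with_disjoint_aliases(small_cohort, tmp_path):
    _, truth, vcf_path, archive_path, _ = small_cohort
    other_cfg = parse_config('[{"field": "AF", "alias": "other_AF", "multiplier": 1000}]')
    other_zip = tmp_path / "other.zip"
    build_archive(vcf_path, other_cfg, other_zip)
    out = tmp_path / "merged.vcf"
    annotate_vcf(vcf_path, [archive_path, str(other_zip)], None, out)
    rec = next(iter(VCF(str(out))))
    assert rec.INFO.get("pop_AF") is not None
    assert rec.INFO.get("other_AF") is not None


def test_duplicate_alias_later_archive_wins(small_cohort, tmp_path, caplog):
    _, truth, vcf_path, archive_path, _ = small_cohort
    # second archive redefines pop_AC as AC+0 but from field AN
    dup_cfg = parse_config('[{"field": "AN", "alias": "pop_AC"}]')
    dup_zip = tmp_path / "dup.zip"
    build_archive(vcf_path, dup_cfg, dup_zip)
    out = tmp_path / "dup.vcf"
    import logging

    with caplog.at_level(logging.WARNING, logger="varzip.annotator"):
        annotate_vcf(vcf_path, [archive_path, str(dup_zip)], None, out)
    assert any("pop_AC" in m for m in caplog.messages)
    for rec, r in zip(VCF(str(out)), truth):
        want = r.info.get("AN", -1)
        assert int(rec.INFO["pop_AC"]) == want
        break


def test_unknown_filter_alias_fails_before_processing(cohort, tmp_path):
    _, _, vcf_path, archive_path, _ = cohort
    with pytest.raises(ExpressionError, match="nonexistent"):
        annotate_vcf(vcf_path, [archive_path], "nonexistent < 1", tmp_path / "x.vcf")


def test_query_chromosome_absent_from_archive(cohort, tmp_path):
    _, _, _, archive_path, _ = cohort
    query = tmp_path / "q.vcf"
    query.write_text(
        "##fileformat=VCFv4.2\n"
        '##contig=<ID=9,length=100000>\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "9\t100\t.\tA\tC\t.\tPASS\t.\n"
    )
    out = tmp_path / "q_out.vcf"
    summary = annotate_vcf(str(query), [archive_path], None, out)
    assert summary.variants_written == 1
    rec = next(iter(VCF(str(out))))
    assert int(rec.INFO["pop_AC"]) == -1
    assert str(rec.INFO["pop_CSQ"]) == "."


def test_multiallelic_and_symbolic_records_pass_through(cohort, tmp_path):
    _, _, _, archive_path, _ = cohort
    query = tmp_path / "q.vcf"
    query.write_text(
        "##fileformat=VCFv4.2\n"
        '##contig=<ID=1,length=100000>\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "1\t100\t.\tA\tC,G\t.\tPASS\t.\n"
        "1\t200\t.\tA\t<DEL>\t.\tPASS\t.\n"
    )
    out = tmp_path / "q_out.vcf"
    summary = annotate_vcf(str(query), [archive_path], None, out)
    assert summary.variants_read == summary.variants_written == 2
    for rec in VCF(str(out)):
        assert int(rec.INFO["pop_AC"]) == -1


def test_null_sink_discards_but_counts(cohort):
    _, truth, vcf_path, archive_path, _ = cohort
    summary = annotate_vcf(vcf_path, [archive_path], "pop_AF < 0.01", "/dev/null")
    assert summary.variants_read == len(truth)
    assert 0 < summary.variants_written < len(truth)


class TestBinCache:
    def _reader(self, archive_path):
        return ArchiveReader(archive_path)

    def test_consecutive_queries_in_one_bin_load_once(self, small_cohort):
        _, _, _, archive_path, _ = small_cohort
        reader = self._reader(archive_path)
        cache = BinCache(reader)
        cache.load_bin_if_needed("1", 0)
        cache.load_bin_if_needed("1", 0)
        assert reader.bin_reads == 1

    def test_alternating_bins_reload_each_time(self, small_cohort):
        _, _, _, archive_path, _ = small_cohort
        reader = self._reader(archive_path)
        cache = BinCache(reader)
        for b in (0, 1, 0, 1):
            cache.load_bin_if_needed("1", b)
        assert reader.bin_reads == 4  # single-slot cache

    def test_sorted_stream_loads_once_per_run_length(self, cohort):
        """One bin read per (chrom, bin) run in a sorted query stream."""
        _, truth, _, archive_path, _ = cohort
        from varzip.archive_io import normalize_chrom
        from varzip.variant_codec import bin_of

        engine = Annotator([archive_path])
        reader = engine.slots[0].reader
        runs = 0
        prev = None
        for r in truth:
            key = (normalize_chrom(r.chrom), bin_of(r.pos)[0])
            if key != prev:
                runs += 1
                prev = key
            engine.annotate_record_values(r.chrom, r.pos, r.ref, r.alt)
        assert reader.bin_reads == runs
        engine.close()
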