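"""Tag registry, rule application semantics, merging, ontology, snapshots."""

import re

import pytest

from metacurate.geo_io import SampleRecord, SeriesRecord
from metacurate.tagging import (
    Annotation,
    AnnotationRule,
    Tag,
    TagRegistry,
    apply_rule,
    bind_ontology,
    canonical_tag_name,
    load_ontology_mapping,
    load_snapshot,
    merge_tags,
    ontology_summary,
    snapshot,
)


def make_rule(regex, mode="match", tag="breast_cancer", field="characteristics_ch1.1"):
    return AnnotationRule(
        series_id="GSE100", field=field, regex=regex, mode=mode,
        tag_name=tag, annotator_id="c1",
    )


class TestRuleValidation:
    def test_regex_must_compile(self):
        with pytest.raises(ValueError, match="compile"):
            make_rule("(unclosed")

    def test_match_mode_rejects_capturing_groups(self):
        with pytest.raises(ValueError, match="match-mode"):
            make_rule("(IDC)")

    def test_match_mode_allows_non_capturing_groups(self):
        make_rule("(?:IDC|ILC)")

    def test_capture_mode_requires_exactly_one_group(self):
        with pytest.raises(ValueError, match="capturing group"):
            make_rule("age: \\d+", mode="capture")
        with pytest.raises(ValueError, match="exactly one"):
            make_rule("(age): (\\d+)", mode="capture")


class TestApplyRule:
    def test_match_mode_tags_only_matching_samples(self, breast_series):
        """The canonical case/control split: an 'IDC' regex marks carcinoma
        samples True and leaves normal-breast samples unannotated."""
        series, samples = breast_series
        annotations, highlights = apply_rule(make_rule("IDC"), series, samples)
        assert {a.sample_id for a in annotations} == {"GSM100", "GSM102"}
        assert all(a.value is True for a in annotations)
        assert set(highlights.spans) == {"GSM100", "GSM102"}

    def test_match_agrees_with_per_sample_regex_scan(self, small_corpus):
        rx = "invasive ductal carcinoma"
        for sim in small_corpus.series:
            rule = AnnotationRule(
                series_id=sim.series.series_id, field="characteristics_ch1.1",
                regex=rx, mode="match", tag_name="case",
            )
            annotations, _ = apply_rule(rule, sim.series, sim.samples)
            expected = {
                s.sample_id
                for s in sim.samples
                if re.search(rx, s.attributes["characteristics_ch1.1"])
            }
            assert {a.sample_id for a in annotations} == expected

    def test_capture_mode_extracts_alternative(self, breast_series):
        series, samples = breast_series
        for s in samples[:2]:
            s.attributes["characteristics_ch1.3"] = "histology: Classic"
        samples[2].attributes["characteristics_ch1.3"] = "histology: MBEN"
        rule = make_rule(
            "(Classic|Desmoplastic|Large cell anaplastic|MBEN)",
            mode="capture", tag="MB_Histology", field="characteristics_ch1.3",
        )
        annotations, _ = apply_rule(rule, series, samples)
        assert {a.sample_id: a.value for a in annotations} == {
            "GSM100": "Classic", "GSM101": "Classic", "GSM102": "MBEN",
        }

    def test_quantitative_capture_parses_number(self, breast_series):
        series, samples = breast_series
        rule = make_rule(
            r"age: (\d+)", mode="capture", tag="Age",
            field="characteristics_ch1.2",
        )
        annotations, _ = apply_rule(
            rule, series, samples, tag=Tag("Age", "quantitative")
        )
        by_id = {a.sample_id: a.value for a in annotations}
        assert by_id["GSM100"] == 50.0

    def test_quantitative_nonnumeric_capture_skipped_with_warning(self):
        series = SeriesRecord("GSE1", sample_ids=["s1"])
        samples = [SampleRecord("s1", "GSE1", attributes={"c": "age: unknown"})]
        rule = AnnotationRule(
            series_id="GSE1", field="c", regex="age: (\\w+)", mode="capture",
            tag_name="Age",
        )
        with pytest.warns(UserWarning, match="not numeric"):
            annotations, _ = apply_rule(
                rule, series, samples, tag=Tag("Age", "quantitative")
            )
        assert annotations == []

    def test_field_absent_from_all_samples_is_error(self, breast_series):
        series, samples = breast_series
        with pytest.raises(ValueError, match="absent"):
            apply_rule(make_rule("IDC", field="nonexistent"), series, samples)

    def test_highlight_spans_lie_within_field_text(self, breast_series):
        series, samples = breast_series
        _, highlights = apply_rule(make_rule("IDC"), series, samples)
        by_id = {s.sample_id: s for s in samples}
        for sid, spans in highlights.spans.items():
            for fname, start, end in spans:
                text = by_id[sid].attributes[fname]
                assert 0 <= start < end <= len(text)
                assert text[start:end] == "IDC"

    def test_one_rule_scales_to_any_series_size(self):
        """A 1,000-sample series needs the same single rule as a 10-sample one."""
        for n in (10, 1000):
            samples = [
                SampleRecord(
                    f"s{i}", "GSE1",
                    attributes={"c": "tumour" if i % 2 else "normal"},
                )
                for i in range(n)
            ]
            series = SeriesRecord("GSE1", sample_ids=[s.sample_id for s in samples])
            rule = AnnotationRule(
                series_id="GSE1", field="c", regex="tumour", mode="match",
                tag_name="case",
            )
            annotations, _ = apply_rule(rule, series, samples)
            assert len(annotations) == n // 2
            assert len(annotations) <= len(samples)


class TestRegistry:
    def test_conflicting_annotation_for_same_sample_tag_annotator(self):
        reg = TagRegistry()
        reg.add_tag(Tag("Age", "quantitative"))
        a1 = Annotation("s1", "GSE1", "Age", 50.0, "c1")
        a2 = Annotation("s1", "GSE1", "Age", 61.0, "c1")
        reg.add_annotations([a1])
        with pytest.raises(ValueError, match="conflicting"):
            reg.add_annotations([a2])
        reg.add_annotations([a1])  # identical duplicate is a no-op
        assert len(reg.annotations) == 1

    def test_tag_names_canonicalized(self):
        assert canonical_tag_name("Breast Cancer") == "breast_cancer"
        reg = TagRegistry()
        reg.add_tag(Tag("Breast Cancer"))
        with pytest.raises(ValueError, match="already registered"):
            reg.add_tag(Tag("breast_cancer"))


def registry_with(tag_annotations):
    reg = TagRegistry()
    for tag, annotations in tag_annotations.items():
        reg.add_tag(Tag(tag))
        reg.add_annotations(
            Annotation(s, "GSE1", tag, True, "c1") for s in annotations
        )
    return reg


class TestMergeTags:
    def test_merge_rekeys_annotations(self):
        reg = registry_with({"Breast_Cancer": ["s1"], "BRCA": ["s2", "s3"]})
        merge_tags(reg, "BRCA", "Breast_Cancer")
        assert "brca" not in reg.tags
        assert {a.sample_id for a in reg.annotations_for("Breast_Cancer")} == {
            "s1", "s2", "s3"
        }

    def test_merge_empty_tag_just_removes_it(self):
        reg = registry_with({"A": [], "B": ["s1"]})
        merge_tags(reg, "A", "B")
        assert set(reg.tags) == {"b"}

    def test_value_kind_mismatch_rejected(self):
        reg = TagRegistry()
        reg.add_tag(Tag("Age", "quantitative"))
        reg.add_tag(Tag("Cancer", "boolean"))
        with pytest.raises(ValueError, match="value kinds differ"):
            merge_tags(reg, "Age", "Cancer")

    def test_merge_order_invariance_on_annotation_multiset(self):
        """A->B then B->C leaves the same annotations as B->C then A->C."""

        def multiset(reg):
            return sorted(
                (a.sample_id, canonical_tag_name(a.tag_name), a.value)
                for a in reg.annotations
            )

        spec = {"A": ["s1"], "B": ["s2"], "C": ["s3"]}
        r1 = registry_with(spec)
        merge_tags(r1, "A", "B")
        merge_tags(r1, "B", "C")
        r2 = registry_with(spec)
        merge_tags(r2, "B", "C")
        merge_tags(r2, "A", "C")
        assert multiset(r1) == multiset(r2)


class TestOntology:
    def test_bind_known_tag(self, tmp_path):
        table = tmp_path / "map.tsv"
        table.write_text("breast_cancer\tDOID\t1612\nAge\tEFO\t0000246\n")
        mapping = load_ontology_mapping(table)
        tag = bind_ontology(Tag("Breast Cancer"), mapping)
        assert tag.ontology_binding == "DOID:1612"

    def test_unmapped_tag_stays_unbound(self):
        tag = bind_ontology(Tag("mystery"), {})
        assert tag.ontology_binding is None

    def test_malformed_term_rejected(self, tmp_path):
        table = tmp_path / "map.tsv"
        table.write_text("breast_cancer\tnot a term\n")
        with pytest.raises(ValueError, match="malformed"):
            load_ontology_mapping(table)

    def test_summary_counts_tags_and_annotations_per_ontology(self):
        tags = [
            Tag("breast_cancer", ontology_binding="DOID:1612"),
            Tag("rcc", ontology_binding="DOID:4450"),
            Tag("Age", ontology_binding="EFO:0000246"),
            Tag("odd_one"),
            Tag("other_odd"),
        ]
        annotations = (
            [Annotation(f"s{i}", "GSE1", "breast_cancer", True) for i in range(3)]
            + [Annotation("s9", "GSE1", "Age", 50.0)]
            + [Annotation("s8", "GSE1", "odd_one", True)]
        )
        df = ontology_summary(tags, annotations).set_index("ontology")
        assert df.loc["DOID", "n_tags"] == 2
        assert df.loc["DOID", "n_annotations"] == 3
        assert df.loc["EFO", "n_annotations"] == 1
        assert df.loc["Unmapped", "n_tags"] == 2
        assert df["n_annotations"].sum() == len(annotations)


class TestSnapshot:
    def _annotations(self):
        return [
            Annotation("s1", "GSE1", "case", True, "c1"),
            Annotation("s2", "GSE1", "case", True, "c1"),
            Annotation("s1", "GSE1", "Age", 50.0, "c1"),
        ]

    def test_round_trip_identity(self, tmp_path):
        annotations = self._annotations()
        snapshot(annotations, tmp_path / "snap", tags=[Tag("case")])
        tags, _, loaded = load_snapshot(tmp_path / "snap")
        assert sorted(loaded, key=str) == sorted(annotations, key=str)
        assert tags[0].name == "case"

    def test_identical_sets_same_hash_any_order(self, tmp_path):
        annotations = self._annotations()
        h1 = snapshot(annotations, tmp_path / "a")
        h2 = snapshot(list(reversed(annotations)), tmp_path / "b")
        assert h1 == h2

    def test_hash_changes_when_any_value_changes(self, tmp_path):
        from dataclasses import replace

        annotations = self._annotations()
        base = snapshot(annotations, tmp_path / "a")
        for i in range(len(annotations)):
            mutated = list(annotations)
            mutated[i] = replace(mutated[i], value="changed")
            assert snapshot(mutated, tmp_path / f"m{i}") != base

    def test_empty_set_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            snapshot([], tmp_path / "snap")
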