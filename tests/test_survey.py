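import numpy as np
import pandas as pd
import pytest

from songscan.annotations import read_selection_table
from songscan.audio_io import AudioClip, write_audio
from songscan.classifier import SVMConfig, train
from songscan.survey import (
    AbundanceRecord,
    abundance_table,
    compare_sites,
    presence_report,
    scan_recordings,
)
from songscan.synthetic import SoundscapeSpec, make_training_corpus, synth_soundscape

from conftest import CORPUS_DETECTOR


@pytest.fixture(scope="module")
def trained_model():
    """SVM trained on a small high-SNR corpus plus sweep distractors."""
    from songscan.synthetic import default_corpus_specs

    specs = default_corpus_specs(n_soundscapes=4, seed=300)
    features, classes, _ = make_training_corpus(specs, detector_cfg=CORPUS_DETECTOR)
    return train(features, (classes > 0).astype(int), SVMConfig(gamma=0.01, cost=10.0))


class TestScanRecordings:
    def test_high_snr_songs_all_positive(self, trained_model, tmp_path):
        spec = SoundscapeSpec(duration=30.0, sample_rate=22050.0, n_target_songs=5,
                              target_snr_db=20.0, seed=900)
        clip, truth = synth_soundscape(spec)
        path = tmp_path / "scape.wav"
        write_audio(clip, path)
        results, skipped = scan_recordings(
            [path], CORPUS_DETECTOR, trained_model, out_dir=tmp_path / "out"
        )
        assert skipped == []
        assert results[0].n_positives == 5

    def test_silence_only_no_candidates(self, trained_model, tmp_path):
        clip = AudioClip(np.zeros(22050 * 5), sample_rate=22050, source_id="quiet")
        path = tmp_path / "quiet.wav"
        write_audio(clip, path)
        results, _ = scan_recordings([path], CORPUS_DETECTOR, trained_model)
        assert results[0].n_candidates == 0
        assert results[0].n_positives == 0

    def test_out_of_band_distractors_no_candidates(self, trained_model, tmp_path):
        sr = 22050.0
        rng = np.random.default_rng(4)
        samples = rng.normal(0, 0.01, int(10 * sr))
        t = np.arange(int(1.0 * sr)) / sr
        samples[int(2 * sr) : int(3 * sr)] += 0.3 * np.sin(2 * np.pi * 8000 * t)
        path = tmp_path / "oob.wav"
        write_audio(AudioClip(samples, sample_rate=sr, source_id="oob"), path)
        results, _ = scan_recordings([path], CORPUS_DETECTOR, trained_model)
        assert results[0].n_candidates == 0

    def test_unreadable_file_skipped(self, trained_model, tmp_path):
        bad = tmp_path / "bad.wav"
        bad.write_bytes(b"garbage")
        results, skipped = scan_recordings([bad], CORPUS_DETECTOR, trained_model)
        assert results == []
        assert skipped == [str(bad)]

    def test_persisted_tables_conserve_positive_counts(self, trained_model, tmp_path):
        spec = SoundscapeSpec(duration=30.0, sample_rate=22050.0, n_target_songs=4,
                              target_snr_db=20.0, seed=901)
        clip, _ = synth_soundscape(spec)
        path = tmp_path / "scape.wav"
        write_audio(clip, path)
        out = tmp_path / "tables"
        results, _ = scan_recordings([path], CORPUS_DETECTOR, trained_model, out_dir=out)
        table = read_selection_table(out / "scape.selections.txt")
        persisted_positives = sum(r.class_label == 1 for r in table)
        assert persisted_positives == results[0].n_positives


class TestPresenceReport:
    def make_result(self, n_pos, source="rec"):
        from songscan.annotations import Selection
        from songscan.survey import ScanResult

        sels = [
            Selection(selection_id=i + 1, source_id=source, begin_time=2.0 * i,
                      end_time=2.0 * i + 1.0, low_freq=1000.0, high_freq=6100.0)
            for i in range(n_pos)
        ]
        return ScanResult(
            source_id=source,
            candidates=sels,
            positives=sels,
            scores=np.arange(n_pos, dtype=float) + 0.5,
            scored_ids=tuple(s.selection_id for s in sels),
        )

    def test_any_positive_presence_true(self):
        report, _ = presence_report([self.make_result(1)])
        assert report["present"] is True

    def test_no_positives_presence_false_empty_review(self):
        report, review = presence_report([self.make_result(0)])
        assert report["present"] is False
        assert review == []

    def test_review_capped_at_top_n_by_score(self):
        report, review = presence_report([self.make_result(68)], top_n=50)
        assert len(review) == 50
        # top scores are the highest selection ids (score = id - 0.5)
        kept_ids = {r.selection.selection_id for r in review}
        assert kept_ids == set(range(19, 69))


class TestAbundance:
    def meta(self):
        return pd.DataFrame(
            {
                "source_id": ["a", "b", "c"],
                "site": ["s1", "s1", "s2"],
                "point": ["p1", "p1", "p2"],
                "minutes": [4.0, 4.0, 5.0],
            }
        )

    def test_exact_division(self):
        records, _, _ = abundance_table({"a": 12, "b": 0, "c": 5}, self.meta())
        by_source = {r.source_id: r for r in records}
        assert by_source["a"].calls_per_minute == pytest.approx(3.0)
        assert by_source["b"].calls_per_minute == 0.0
        assert by_source["c"].calls_per_minute == pytest.approx(1.0)

    def test_point_mean(self):
        records, point_means, _ = abundance_table({"a": 12, "b": 4}, self.meta())
        row = point_means[(point_means["site"] == "s1") & (point_means["point"] == "p1")]
        assert row["calls_per_minute"].iloc[0] == pytest.approx(2.0)

    def test_missing_metadata_names_source(self):
        with pytest.raises(KeyError, match="zzz"):
            abundance_table({"zzz": 1}, self.meta())

    def test_zero_minutes_rejected(self):
        with pytest.raises(ValueError):
            AbundanceRecord(source_id="x", site="s", point="p", n_detections=1, minutes=0.0)


def simulated_abundance(site_means, sd, seed, n_points_per_site=3, n_records_per_point=4):
    rng = np.random.default_rng(seed)
    rows = []
    for s, mu in enumerate(site_means):
        for p in range(n_points_per_site):
            for _ in range(n_records_per_point):
                rows.append(
                    {
                        "site": f"site{s}",
                        "point": f"s{s}p{p}",
                        "calls_per_minute": max(0.0, rng.normal(mu, sd)),
                    }
                )
    return pd.DataFrame(rows)


class TestCompareSites:
    def test_well_separated_sites_prefer_site_model(self):
        frame = simulated_abundance([1.0, 5.0], sd=0.2, seed=0)
        result = compare_sites(frame)
        assert result.preferred == "site"
        assert result.delta_aic > 2.0

    def test_null_simulation_mostly_equivalent(self):
        verdicts = []
        for seed in range(40):
            frame = simulated_abundance([2.0, 2.0], sd=0.5, seed=seed)
            verdicts.append(compare_sites(frame).preferred)
        ok = sum(v in ("equivalent", "null") for v in verdicts)
        assert ok >= 36  # >= 90%

    def test_single_site_errors(self):
        frame = simulated_abundance([2.0], sd=0.5, seed=1)
        with pytest.raises(ValueError, match="2 sites"):
            compare_sites(frame)

    def test_single_point_per_site_errors(self):
        frame = simulated_abundance([1.0, 2.0], sd=0.5, seed=1, n_points_per_site=1)
        with pytest.raises(ValueError, match="points"):
            compare_sites(frame)

    def test_preferred_equivalent_iff_delta_below_2(self):
        frame = simulated_abundance([1.0, 5.0], sd=0.2, seed=0)
        result = compare_sites(frame)
        assert (result.preferred == "equivalent") == (abs(result.delta_aic) < 2.0)
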