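import hashlib
from pathlib import Path

import numpy as np
import pytest

from tadconcord import (
    RunConfig,
    SyntheticSpec,
    compare_sets,
    generate_matrix,
    generate_partition,
    jitter,
    run_compare,
    run_normalize,
    write_dense_matrix,
    write_tad_set,
)


def tree_digest(directory):
    """Digest of every file's name and bytes under a directory."""
    h = hashlib.sha256()
    for p in sorted(Path(directory).rglob("*")):
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()


@pytest.fixture
def bed_files(tmp_path):
    spec = SyntheticSpec(n_bins=200, min_size=5, max_size=25, seed=11)
    base = generate_partition(spec, label="base")
    variants = {
        "base": base,
        "near": jitter(base, 1, seed=1).with_label("near"),
        "far": jitter(base, 6, seed=2).with_label("far"),
        "other": generate_partition(
            SyntheticSpec(n_bins=200, min_size=5, max_size=25, seed=99),
            label="other",
        ),
    }
    paths = {}
    for name, ts in variants.items():
        p = tmp_path / f"{name}.bed"
        write_tad_set(ts, p, units="bp")
        paths[name] = str(p)
    return variants, paths


def make_config(paths, out_dir, **kw):
    defaults = dict(
        tad_paths=tuple(paths.values()),
        labels=tuple(paths.keys()),
        chrom="chrS",
        resolution=40_000,
        n_bins=200,
        out_dir=str(out_dir),
    )
    defaults.update(kw)
    return RunConfig(**defaults)


class TestRunCompare:
    def test_report_contains_all_analyses(self, bed_files, tmp_path):
        variants, paths = bed_files
        config = make_config(paths, tmp_path / "run1")
        report = run_compare(config)
        out = Path(config.out_dir)
        for name in (
            "counts.csv", "size_summaries.csv", "moc_matrix.csv",
            "moc_averages.csv", "moc_one_vs_all.csv", "provenance.json",
            "embedding_pca.csv", "embedding_tsne.csv",
        ):
            assert (out / name).exists(), name
        for label in paths:
            assert (out / f"shared_boundaries_vs_{label}.csv").exists()
            assert (out / f"shared_domains_vs_{label}.csv").exists()
        for t in config.tolerances:
            assert (out / f"boundary_profile_pct_t{t}.csv").exists()
        # labels propagate in input order everywhere
        labels = list(paths)
        assert report.counts.index.tolist() == labels
        assert report.moc_values.index.tolist() == labels
        assert report.size_summaries.index.tolist() == labels

    def test_identical_datasets_fully_concordant(self, tmp_path):
        spec = SyntheticSpec(n_bins=150, seed=4)
        ts = generate_partition(spec, label="x")
        p1, p2 = tmp_path / "a.bed", tmp_path / "b.bed"
        write_tad_set(ts, p1)
        write_tad_set(ts, p2)
        config = RunConfig(
            tad_paths=(str(p1), str(p2)), labels=("a", "b"),
            chrom="chrS", resolution=40_000, n_bins=150,
            out_dir=str(tmp_path / "out"),
        )
        report = run_compare(config, write=False)
        assert report.counts["a"] == report.counts["b"] == len(ts)
        np.testing.assert_allclose(report.moc_values.to_numpy(), 1.0, atol=1e-12)
        prof = report.boundary_profiles[0]
        assert prof.counts[1].sum() == prof.counts.sum().sum()  # all shared

    def test_byte_identical_reruns(self, bed_files, tmp_path):
        _, paths = bed_files
        d1, d2 = tmp_path / "r1", tmp_path / "r2"
        c1 = make_config(paths, d1)
        run_compare(c1)
        # a separate config object differing only in out_dir
        run_compare(make_config(paths, d2))
        h1 = hashlib.sha256()
        h2 = hashlib.sha256()
        for d, h in ((d1, h1), (d2, h2)):
            for p in sorted(Path(d).iterdir()):
                if p.name != "provenance.json":  # echoes out_dir itself
                    h.update(p.name.encode())
                    h.update(p.read_bytes())
        assert h1.hexdigest() == h2.hexdigest()

    def test_same_out_dir_rerun_identical_including_provenance(
        self, bed_files, tmp_path
    ):
        _, paths = bed_files
        d = tmp_path / "rr"
        config = make_config(paths, d)
        run_compare(config)
        first = tree_digest(d)
        run_compare(config)
        assert tree_digest(d) == first

    def test_single_dataset_rejected(self, bed_files, tmp_path):
        _, paths = bed_files
        with pytest.raises(ValueError, match="at least 2"):
            RunConfig(
                tad_paths=(paths["base"],), labels=("base",),
                chrom="chrS", resolution=40_000, n_bins=200,
            )

    def test_duplicate_labels_rejected(self, bed_files):
        _, paths = bed_files
        with pytest.raises(ValueError, match="unique"):
            RunConfig(
                tad_paths=(paths["base"], paths["near"]), labels=("x", "x"),
                chrom="chrS", resolution=40_000, n_bins=200,
            )

    def test_parse_failure_names_dataset(self, bed_files, tmp_path):
        _, paths = bed_files
        bad = tmp_path / "bad.bed"
        bad.write_text("chrS\t10\t5\n")
        config = RunConfig(
            tad_paths=(paths["base"], str(bad)), labels=("base", "bad"),
            chrom="chrS", resolution=40_000, n_bins=200,
            out_dir=str(tmp_path / "never"),
        )
        with pytest.raises(RuntimeError, match="'bad'"):
            run_compare(config)
        assert not (tmp_path / "never").exists()  # no partial results

    def test_compare_sets_in_memory(self, bed_files):
        variants, _ = bed_files
        report = compare_sets(list(variants.values()), tolerances=(0, 1))
        assert report.moc_averages["near"] > report.moc_averages["other"]


class TestRunNormalize:
    def test_writes_one_file_per_method(self, tmp_path):
        ts = generate_partition(SyntheticSpec(n_bins=50, seed=0))
        write_dense_matrix(generate_matrix(ts, seed=1), tmp_path / "m.txt")
        written = run_normalize(
            tmp_path / "m.txt", ["vc", "kr", "ice"], tmp_path / "norm"
        )
        assert set(written) == {"VC", "KR", "ICE"}
        assert (tmp_path / "norm" / "convergence.log").exists()
        for path in written.values():
            v = np.loadtxt(path)
            assert np.allclose(v, v.T) and (v >= 0).all()

    def test_vc_output_matches_closed_form(self, tmp_path):
        (tmp_path / "m.txt").write_text("4 2\n2 1\n")
        written = run_normalize(tmp_path / "m.txt", ["VC"], tmp_path / "n")
        np.testing.assert_allclose(
            np.loadtxt(written["VC"]), np.full((2, 2), 2.25), rtol=1e-9
        )

    def test_failed_method_logged_not_fatal(self, tmp_path):
        ts = generate_partition(SyntheticSpec(n_bins=40, seed=2))
        write_dense_matrix(generate_matrix(ts, seed=3), tmp_path / "m.txt")
        written = run_normalize(
            tmp_path / "m.txt", ["ice", "vc"], tmp_path / "n",
            tol=1e-15, max_iter=2,
        )
        assert "VC" in written and "ICE" not in written
        log = (tmp_path / "n" / "convergence.log").read_text()
        assert "FAILED" in log

    def test_empty_method_list_rejected(self, tmp_path):
        (tmp_path / "m.txt").write_text("1 0\n0 1\n")
        with pytest.raises(ValueError, match="no normalization"):
            run_normalize(tmp_path / "m.txt", [], tmp_path / "n")
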