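import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dmmrkit import synthetic_data
from dmmrkit.io_formats import SiteSet
from dmmrkit.shape_topology import (
    BASE_FEATURES,
    FEATURES,
    STEP_FEATURES,
    PentamerShape,
    PercentileEnvelope,
    ShapeProfile,
    ShapeTable,
    UnknownPentamerError,
    build_envelope,
    departure_score,
    encode_methylation,
    methylation_delta,
    predict_shape,
    read_shape_table,
    write_shape_table,
)


class TestEncode:
    def test_single_cpg(self):
        eseq = encode_methylation("ACGT", [1])
        assert eseq.encoded == "AMWT"

    def test_no_positions_identity(self):
        assert encode_methylation("ACGT").encoded == "ACGT"

    def test_non_cpg_position_rejected(self):
        with pytest.raises(ValueError, match="CpG"):
            encode_methylation("ACAT", [1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            encode_methylation("ACG", [2])

    def test_reverse_complement_maps_m_to_w(self):
        eseq = encode_methylation("ACGT", [1])
        rc = eseq.reverse_complement()
        assert rc.encoded == "AMWT"  # palindromic around the CpG
        assert rc.methylated_cpgs == (1,)


def _constant_table(value=1.0):
    bases = "ACGTMW"
    shape = PentamerShape(
        mgw=value, prot=value, helt1=value, helt2=value,
        roll1=value, roll2=value,
    )
    values = {
        a + b + c + d + e: shape
        for a in bases for b in bases for c in bases
        for d in bases for e in bases
    }
    return ShapeTable(values=values)


class TestPredict:
    def test_length_5_window_arithmetic(self, shape_table):
        profile = predict_shape(encode_methylation("ACGTA"), shape_table)
        for name in BASE_FEATURES:
            defined = ~np.isnan(profile.features[name])
            assert defined.sum() == 1
            assert defined[2]
        for name in STEP_FEATURES:
            defined = ~np.isnan(profile.features[name])
            assert defined.sum() == 2
            assert defined[1] and defined[2]

    def test_too_short_rejected(self, shape_table):
        with pytest.raises(ValueError):
            predict_shape(encode_methylation("ACGT"), shape_table)

    def test_homopolymer_constant_table_constant_profile(self):
        profile = predict_shape(
            encode_methylation("A" * 12), _constant_table(2.5)
        )
        for name in FEATURES:
            values = profile.features[name]
            assert np.allclose(values[~np.isnan(values)], 2.5)

    def test_interior_steps_average_two_pentamers(self):
        # 6-mer: step 2 is covered by both pentamers
        table = _constant_table()
        values = dict(table.values)
        values["AAAAA"] = PentamerShape(1, 1, 10.0, 20.0, 1, 1)
        values["AAAAC"] = PentamerShape(1, 1, 30.0, 40.0, 1, 1)
        table = ShapeTable(values=values)
        profile = predict_shape(encode_methylation("AAAAAC"), table)
        helt = profile.features["HelT"]
        assert helt[1] == pytest.approx(10.0)  # single cover
        assert helt[2] == pytest.approx((20.0 + 30.0) / 2)
        assert helt[3] == pytest.approx(40.0)

    def test_unknown_pentamer_named(self):
        table = ShapeTable(values={"AAAAA": PentamerShape(1, 1, 1, 1, 1, 1)})
        with pytest.raises(UnknownPentamerError, match="AAACA"):
            predict_shape(encode_methylation("AAACAAA"), table)

    def test_reverse_complement_profiles_mirrored(self, shape_table):
        # brute-force oracle: the generated table is strand-symmetric, so
        # the profile of the reverse complement is the reversed profile
        seq = "AACGTTAGCCA"
        fwd = predict_shape(encode_methylation(seq), shape_table)
        rc = predict_shape(
            encode_methylation(seq).reverse_complement(), shape_table
        )
        for name in BASE_FEATURES:
            np.testing.assert_allclose(
                rc.features[name], fwd.features[name][::-1]
            )
        for name in STEP_FEATURES:
            np.testing.assert_allclose(
                rc.features[name], fwd.features[name][::-1]
            )

    def test_report_window(self, shape_table):
        seq = "ACGTACGTACGTACGTACGT"
        full = predict_shape(encode_methylation(seq), shape_table)
        windowed = predict_shape(
            encode_methylation(seq), shape_table, report=(5, 15)
        )
        np.testing.assert_allclose(
            windowed.features["MGW"], full.features["MGW"][5:15]
        )
        np.testing.assert_allclose(
            windowed.features["HelT"], full.features["HelT"][5:14]
        )


class TestDelta:
    def test_no_methylation_all_zero(self, shape_table):
        delta = methylation_delta("ACGTACGTACGT", [], shape_table)
        for name in FEATURES:
            values = delta[name]
            assert np.allclose(values[~np.isnan(values)], 0.0)

    def test_locality_around_central_cpg(self, shape_table):
        seq = "A" * 19 + "CG" + "A" * 20  # 41-mer, CpG at 19-20
        delta = methylation_delta(seq, [19], shape_table)
        for name in BASE_FEATURES:
            nz = np.flatnonzero(np.nan_to_num(delta[name]))
            assert all(17 <= i <= 22 for i in nz)
        for name in STEP_FEATURES:
            nz = np.flatnonzero(np.nan_to_num(delta[name]))
            assert all(16 <= i <= 22 for i in nz)

    def test_generator_defined_signs(self, shape_table):
        seq = "A" * 19 + "CG" + "A" * 20
        delta = methylation_delta(seq, [19], shape_table)
        prot = delta["ProT"][~np.isnan(delta["ProT"])]
        roll = delta["Roll"][~np.isnan(delta["Roll"])]
        assert prot.min() < 0 and prot.max() <= 0  # ProT lowered
        assert roll.max() > 0 and roll.min() >= 0  # Roll raised
        mgw = delta["MGW"][~np.isnan(delta["MGW"])]
        assert np.allclose(mgw, 0.0)  # untouched feature

    @settings(max_examples=25, deadline=None)
    @given(data=st.data())
    def test_locality_property(self, shape_table, data):
        rng_seed = data.draw(st.integers(0, 10_000))
        rng = np.random.default_rng(rng_seed)
        seq = "".join(rng.choice(list("ACGT"), size=30))
        cpgs = [i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"]
        if not cpgs:
            return
        pos = cpgs[data.draw(st.integers(0, len(cpgs) - 1))]
        delta = methylation_delta(seq, [pos], shape_table)
        for name in BASE_FEATURES:
            nz = np.flatnonzero(np.nan_to_num(delta[name]))
            assert all(pos - 2 <= i <= pos + 3 for i in nz)
        for name in STEP_FEATURES:
            nz = np.flatnonzero(np.nan_to_num(delta[name]))
            assert all(pos - 3 <= i <= pos + 3 for i in nz)


class TestEnvelope:
    def test_identical_sites_collapse(self, shape_table):
        sites = SiteSet(name="x", sequences=("ACGTACGTAC",) * 100)
        env = build_envelope(sites, shape_table)
        for name in FEATURES:
            per = env.percentiles[name]
            for q in (25, 50, 75, 95):
                np.testing.assert_array_equal(
                    np.nan_to_num(per[5]), np.nan_to_num(per[q])
                )

    def test_floor_rejected(self, shape_table):
        sites = SiteSet(name="x", sequences=("ACGTACGT", "TTGGCCAA"))
        with pytest.raises(ValueError, match="floor"):
            build_envelope(sites, shape_table)
        env = build_envelope(sites, shape_table, allow_small=True)
        assert env.n_sites == 2

    def test_median_matches_sort_oracle(self, shape_table):
        sites = synthetic_data.gen_motif_sites("NNNNNNNN", 1000, 17)
        env = build_envelope(sites, shape_table)
        for name in FEATURES:
            matrix = env.reference[name]
            defined = ~np.isnan(matrix[0])
            for i in np.flatnonzero(defined):
                column = np.sort(matrix[:, i])
                oracle = (column[499] + column[500]) / 2
                assert env.percentiles[name][50][i] == pytest.approx(oracle)

    def test_percentiles_monotone(self, shape_table):
        sites = synthetic_data.gen_motif_sites("NNNNNNNNNN", 200, 23)
        env = build_envelope(sites, shape_table)
        for name in FEATURES:
            per = env.percentiles[name]
            defined = ~np.isnan(per[5])
            for lo, hi in zip((5, 25, 50, 75), (25, 50, 75, 95)):
                assert (per[lo][defined] <= per[hi][defined] + 1e-12).all()

    def test_json_round_trip(self, shape_table, tmp_path):
        sites = synthetic_data.gen_motif_sites("NNNNNN", 50, 3)
        env = build_envelope(sites, shape_table)
        path = tmp_path / "env.json"
        env.to_json(path)
        again = PercentileEnvelope.from_json(path)
        assert again.n_sites == env.n_sites
        for name in FEATURES:
            np.testing.assert_allclose(
                again.reference[name], env.reference[name]
            )


def _median_profile(env):
    return ShapeProfile(
        features={name: env.percentiles[name][50].copy() for name in FEATURES}
    )


def make_continuous_envelope(seed, n_sites=201, length=10):
    """Envelope backed by continuous (tie-free) reference values, where the
    rank identities hold exactly without tie residuals."""
    rng = np.random.default_rng(seed)
    reference = {}
    percentiles = {}
    for name in FEATURES:
        width = length if name in ("MGW", "ProT") else length - 1
        matrix = rng.normal(size=(n_sites, width))
        if name in ("MGW", "ProT"):
            matrix[:, :2] = np.nan
            matrix[:, -2:] = np.nan
        else:
            matrix[:, 0] = np.nan
            matrix[:, -1] = np.nan
        defined = ~np.isnan(matrix[0])
        per = {}
        for q in (5, 25, 50, 75, 95):
            arr = np.full(width, np.nan)
            arr[defined] = np.percentile(matrix[:, defined], q, axis=0)
            per[q] = arr
        reference[name] = matrix
        percentiles[name] = per
    return PercentileEnvelope(
        motif="synthetic", n_sites=n_sites,
        percentiles=percentiles, reference=reference,
    )


@pytest.fixture(scope="module")
def env(shape_table):
    sites = synthetic_data.gen_motif_sites("NNNNNNNNNN", 201, 29)
    return build_envelope(sites, shape_table)


class TestDeparture:

    def test_median_profile_scores_zero(self):
        env = make_continuous_envelope(1)
        score = departure_score(_median_profile(env), env)
        for name in FEATURES:
            assert score.mean_rank_deviation[name] == pytest.approx(0.0, abs=1e-9)
            assert score.envelope_exceedance[name] == 0.0

    def test_median_profile_near_zero_with_ties(self, env):
        # pentamer lookups tie across sites; the rank residual stays small
        score = departure_score(_median_profile(env), env)
        for name in FEATURES:
            assert score.mean_rank_deviation[name] <= 0.02
            assert score.envelope_exceedance[name] == 0.0

    def test_above_p95_everywhere_exceeds_fully(self):
        env = make_continuous_envelope(2)
        features = {
            name: env.percentiles[name][95] + 1.0 for name in FEATURES
        }
        score = departure_score(ShapeProfile(features=features), env)
        for name in FEATURES:
            assert score.envelope_exceedance[name] == pytest.approx(1.0)

    def test_above_all_references_full_deviation(self):
        env = make_continuous_envelope(2)
        features = {}
        for name in FEATURES:
            ref = env.reference[name]
            defined = ~np.isnan(ref[0])
            arr = np.full(ref.shape[1], np.nan)
            arr[defined] = ref[:, defined].max(axis=0) + 1.0
            features[name] = arr
        score = departure_score(ShapeProfile(features=features), env)
        for name in FEATURES:
            assert score.mean_rank_deviation[name] == pytest.approx(1.0)
            assert score.envelope_exceedance[name] == pytest.approx(1.0)

    def test_invariant_under_adding_median_sites(self):
        env = make_continuous_envelope(3)
        query = _median_profile(env)
        before = departure_score(query, env)
        medians = {name: env.percentiles[name][50] for name in FEATURES}
        padded_ref = {
            name: np.vstack([env.reference[name]] + [medians[name]] * 10)
            for name in FEATURES
        }
        padded = PercentileEnvelope(
            motif=env.motif,
            n_sites=env.n_sites + 10,
            percentiles=env.percentiles,
            reference=padded_ref,
        )
        after = departure_score(query, padded)
        for name in FEATURES:
            assert after.mean_rank_deviation[name] == pytest.approx(
                before.mean_rank_deviation[name], abs=1e-9
            )

    def test_length_mismatch_rejected(self, env, shape_table):
        short = predict_shape(encode_methylation("ACGTACG"), shape_table)
        with pytest.raises(ValueError, match="positions"):
            departure_score(short, env)

    @pytest.mark.parametrize("seed", range(1, 11))
    def test_methylated_motif_departs_more(self, shape_table, seed):
        config = synthetic_data.SimulationConfig(seed=seed)
        sites = synthetic_data.gen_motif_sites(
            config.motif_consensus, 200, seed + 100
        )
        env = build_envelope(sites, shape_table)
        promoter = synthetic_data.gen_promoter(config)
        start = promoter.motif_start
        end = start + len(promoter.motif_sequence)
        scores = {}
        for label, cpgs in (
            ("unmethylated", ()),
            ("methylated", promoter.cpg_positions),
        ):
            profile = predict_shape(
                encode_methylation(promoter.sequence, cpgs),
                shape_table,
                report=(start, end),
            )
            scores[label] = departure_score(profile, env)
        for name in ("ProT", "Roll"):
            assert (
                scores["methylated"].mean_rank_deviation[name]
                > scores["unmethylated"].mean_rank_deviation[name]
            )


class TestShapeTableIo:
    def test_round_trip(self, shape_table, tmp_path):
        path = tmp_path / "table.tsv"
        write_shape_table(shape_table, path)
        again = read_shape_table(path)
        assert len(again.values) == len(shape_table.values)
        for penta in ("ACGTA", "MWACG", "TTTTT"):
            a, b = shape_table.values[penta], again.values[penta]
            assert a.mgw == pytest.approx(b.mgw)
            assert a.roll2 == pytest.approx(b.roll2)
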