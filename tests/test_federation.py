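"""Protocol round mechanics: encryption, combination, aggregation, decryption."""

import numpy as np
import pytest

from shefl.crypto_ring import FixedPointCodec, RingTensor, default_codec, encode
from shefl.federation import (
    CryptoConfig,
    EncryptedSubmission,
    FederationScenario,
    ModelUpdate,
    decrypt_global,
    encrypt_update,
    fedavg_coefficients,
    holder_combine,
    local_train_round,
    run_federation,
    server_aggregate,
)
from shefl.synthetic_data import FeatureBagConfig, generate_feature_site
from shefl.tasks import ClfTrainConfig, MLPConfig


@pytest.fixture(scope="module")
def codec():
    return default_codec()


@pytest.fixture(scope="module")
def small_scenario(codec):
    return FederationScenario(
        task="feature-classification",
        n_sites=3,
        rounds=1,
        seed=0,
        crypto=CryptoConfig(codec=codec, mask_seed=0),
        model_config=MLPConfig(widths=(8, 4, 2)),
        train_config=ClfTrainConfig(),
        data_config=FeatureBagConfig(
            dim=8, n_active=4, patients_per_site=4, tiles_per_patient=6,
            test_patients=8,
        ),
    )


def _update(params, site=0, rnd=0, n=4):
    return ModelUpdate(parameters=params, site_id=site, round_index=rnd,
                       sample_count=n)


class TestScenarioValidation:
    def test_too_many_sites_for_modulus(self, codec):
        with pytest.raises(ValueError):
            FederationScenario(
                task="feature-classification",
                n_sites=5,
                crypto=CryptoConfig(codec=codec),
            )

    def test_unknown_task_rejected(self):
        with pytest.raises(ValueError):
            FederationScenario(task="pose-estimation")

    def test_weighting_options(self, small_scenario):
        assert np.allclose(
            fedavg_coefficients(small_scenario, [4, 4, 4]), 1 / 3
        )
        prop = FederationScenario(
            task="feature-classification", n_sites=3,
            fedavg_weights="size-proportional",
        )
        assert np.allclose(
            fedavg_coefficients(prop, [1, 1, 2]), [0.25, 0.25, 0.5]
        )


class TestLocalTraining:
    def test_zero_lr_returns_input_weights(self, small_scenario):
        sc = FederationScenario(
            task="feature-classification", n_sites=3, seed=0,
            model_config=MLPConfig(widths=(8, 4, 2)),
            train_config=ClfTrainConfig(lr=0.0),
            data_config=small_scenario.data_config,
        )
        from shefl.federation import _build_model

        model = _build_model(sc)
        weights = {k: v.copy() for k, v in model.parameters().items()}
        data = generate_feature_site(sc.resolved_data_config(), 0, 0)
        update = local_train_round(weights, data, sc, 0, 0)
        for k in weights:
            assert np.array_equal(update.parameters[k], weights[k])

    def test_deterministic_given_seed(self, small_scenario):
        data = generate_feature_site(small_scenario.resolved_data_config(), 0, 0)
        from shefl.federation import _build_model

        model = _build_model(small_scenario)
        weights = {k: v.copy() for k, v in model.parameters().items()}
        a = local_train_round(weights, data, small_scenario, 0, 0)
        b = local_train_round(weights, data, small_scenario, 0, 0)
        for k in a.parameters:
            assert np.array_equal(a.parameters[k], b.parameters[k])

    def test_empty_dataset_rejected(self, small_scenario):
        from shefl.synthetic_data import FeatureSiteData

        empty = FeatureSiteData(
            site_id=0, features=np.zeros((0, 5, 8)), labels=np.zeros(0, int)
        )
        with pytest.raises(ValueError):
            local_train_round({}, empty, small_scenario, 0, 0)


class TestEncryptionRound:
    def test_own_messages_reconstruct_scaled_update(self, small_scenario, rng):
        params = {"w": rng.normal(size=(3, 2)), "b": rng.normal(size=2)}
        coeff = 1 / 3
        messages = encrypt_update(_update(params), small_scenario, coeff)
        codec = small_scenario.crypto.codec
        Q = codec.modulus.Q
        for name, truth in params.items():
            acc = np.zeros(truth.size, dtype=np.int64)
            for h in range(3):
                acc = np.mod(acc + messages[h][name].values, Q)
            rt = RingTensor(shape=truth.shape, values=acc)
            from shefl.crypto_ring import decode

            assert np.max(np.abs(decode(rt, codec) - coeff * truth)) <= 0.5e-13

    def test_zero_update_reconstructs_to_zero(self, small_scenario):
        params = {"w": np.zeros((2, 2))}
        messages = encrypt_update(_update(params), small_scenario, 1 / 3)
        Q = small_scenario.crypto.codec.modulus.Q
        acc = sum(messages[h]["w"].values for h in range(3)) % Q
        assert np.all(acc == 0)

    def test_mask_seeds_change_messages_not_reconstruction(self, codec, small_scenario, rng):
        params = {"w": rng.normal(size=(4,))}
        import dataclasses

        sc2 = dataclasses.replace(
            small_scenario, crypto=CryptoConfig(codec=codec, mask_seed=99)
        )
        m1 = encrypt_update(_update(params), small_scenario, 0.5)
        m2 = encrypt_update(_update(params), sc2, 0.5)
        assert not np.array_equal(m1[0]["w"].values, m2[0]["w"].values)
        Q = codec.modulus.Q
        r1 = sum(m1[h]["w"].values for h in range(3)) % Q
        r2 = sum(m2[h]["w"].values for h in range(3)) % Q
        assert np.array_equal(r1, r2)

    def test_overflow_names_the_tensor(self, small_scenario):
        params = {"huge": np.array([1e100])}
        with pytest.raises(OverflowError, match="huge"):
            encrypt_update(_update(params), small_scenario, 1.0)


class TestHolderAndServer:
    def _hand_worked_submissions(self, q97):
        """Two sites, scalar secrets 10 and 20, Q = 97, two holders."""
        scenario = FederationScenario(
            task="feature-classification",
            n_sites=2,
            crypto=CryptoConfig(
                codec=FixedPointCodec(precision=0, modulus=q97)
            ),
        )
        # site 0 splits 10 as (30, 77); site 1 splits 20 as (50, 67)
        def rt(v):
            return RingTensor(shape=(1,), values=np.array([v]))

        received_h0 = {0: {"w": rt(30)}, 1: {"w": rt(50)}}
        received_h1 = {0: {"w": rt(77)}, 1: {"w": rt(67)}}
        s0 = holder_combine(0, received_h0, scenario)
        s1 = holder_combine(1, received_h1, scenario)
        return scenario, s0, s1

    def test_holder_combine_hand_worked(self, q97):
        _, s0, s1 = self._hand_worked_submissions(q97)
        assert int(s0.masked["w"].values[0]) == 80  # (30 + 50) mod 97
        assert int(s1.masked["w"].values[0]) == 47  # (77 + 67) mod 97

    def test_aggregate_reconstructs_sum_of_secrets(self, q97):
        scenario, s0, s1 = self._hand_worked_submissions(q97)
        agg = server_aggregate([s0, s1])
        assert int(agg["w"][0]) == 127  # plain integer sum, no reduction
        out = decrypt_global(agg, scenario.crypto.codec)
        assert out["w"][0] == pytest.approx(30.0)  # (10 + 20) mod 97

    def test_missing_sender_rejected(self, q97):
        scenario, _, _ = self._hand_worked_submissions(q97)

        def rt(v):
            return RingTensor(shape=(1,), values=np.array([v]))

        with pytest.raises(ValueError, match="missing"):
            holder_combine(0, {0: {"w": rt(1)}}, scenario)

    def test_single_submission_is_identity(self, rng):
        sub = EncryptedSubmission(
            holder_id=0,
            masked={"w": RingTensor(shape=(3,), values=rng.integers(0, 97, 3))},
        )
        agg = server_aggregate([sub])
        assert np.array_equal(agg["w"], sub.masked["w"].reshaped())

    def test_aggregate_permutation_invariant(self, q97):
        _, s0, s1 = self._hand_worked_submissions(q97)
        a = server_aggregate([s0, s1])
        b = server_aggregate([s1, s0])
        assert np.array_equal(a["w"], b["w"])


class TestDecryptGlobal:
    def test_identical_weights_are_a_fixed_point(self, codec):
        sc = FederationScenario(
            task="feature-classification", n_sites=3,
            crypto=CryptoConfig(codec=codec),
        )
        w = np.array([0.25, -1.5, 3.125])
        messages = [
            encrypt_update(_update({"w": w}, site=s), sc, 1 / 3)
            for s in range(3)
        ]
        subs = [
            holder_combine(h, {s: messages[s][h] for s in range(3)}, sc)
            for h in range(3)
        ]
        out = decrypt_global(server_aggregate(subs), codec)
        # 10^-p, plus a float64 ulp at the weight's magnitude
        assert np.max(np.abs(out["w"] - w)) <= 1e-13 + np.spacing(4.0)

    def test_mean_of_0_1_2_is_1(self, codec):
        sc = FederationScenario(
            task="feature-classification", n_sites=3,
            crypto=CryptoConfig(codec=codec),
        )
        messages = [
            encrypt_update(
                _update({"w": np.array([float(s)])}, site=s), sc, 1 / 3
            )
            for s in range(3)
        ]
        subs = [
            holder_combine(h, {s: messages[s][h] for s in range(3)}, sc)
            for h in range(3)
        ]
        out = decrypt_global(server_aggregate(subs), codec)
        assert out["w"][0] == pytest.approx(1.0, abs=3e-13)


@pytest.fixture(scope="module")
def tiny():
    return dict(
        task="feature-classification",
        n_sites=3,
        rounds=2,
        seed=5,
        model_config=MLPConfig(widths=(8, 4, 2)),
        train_config=ClfTrainConfig(lr=1e-3, batch_size=8),
        data_config=FeatureBagConfig(
            dim=8, n_active=4, patients_per_site=4, tiles_per_patient=6,
            test_patients=10,
        ),
    )


class TestRunFederation:
    def test_fl_and_shefl_agree_per_aggregation(self, tiny, codec):
        she = run_federation(
            FederationScenario(**tiny, crypto=CryptoConfig(codec=codec)),
            "shefl",
            record_weights=True,
        )
        fl = run_federation(FederationScenario(**tiny), "fl", record_weights=True)
        # every SHEFL aggregation matches the plaintext FedAvg of the same
        # updates within N x 10^-p
        for entry in she.rounds:
            assert entry["transcript"]["plaintext_gap"] <= 3 * 1e-13
        # round 1 of the two runs agrees before drift can compound
        w_she, w_fl = she.rounds[0]["weights"], fl.rounds[0]["weights"]
        gap = max(np.abs(w_she[k] - w_fl[k]).max() for k in w_fl)
        assert gap <= 3e-13
        assert she.rounds[-1]["metric"] == pytest.approx(
            fl.rounds[-1]["metric"], abs=1e-4
        )

    def test_single_site_shefl_degenerates_to_local(self, codec):
        base = dict(
            task="feature-classification",
            n_sites=1,
            rounds=2,
            seed=3,
            model_config=MLPConfig(widths=(8, 4, 2)),
            train_config=ClfTrainConfig(lr=1e-3, batch_size=8),
            data_config=FeatureBagConfig(
                dim=8, n_active=4, patients_per_site=4, tiles_per_patient=6,
                test_patients=10,
            ),
        )
        she = run_federation(
            FederationScenario(**base, crypto=CryptoConfig(codec=codec)),
            "shefl",
            record_weights=True,
        )
        loc = run_federation(FederationScenario(**base), "local")
        # with one site FedAvg is the identity: SHEFL equals plain local
        # training up to one encode/decode rounding per round
        assert she.rounds[-1]["metric"] == pytest.approx(
            loc.rounds[-1]["metric"][0], abs=1e-6
        )

    def test_server_view_changes_with_mask_seed_but_model_does_not(
        self, tiny, codec
    ):
        runs = []
        for mask_seed in (0, 1):
            sc = FederationScenario(
                **tiny, crypto=CryptoConfig(codec=codec, mask_seed=mask_seed)
            )
            runs.append(
                run_federation(
                    sc, "shefl", record_server_view=True, record_weights=True
                )
            )
        a, b = runs
        for ra, rb in zip(a.rounds, b.rounds):
            va = ra["transcript"]["server_view"]
            vb = rb["transcript"]["server_view"]
            for sa, sb in zip(va["submissions"], vb["submissions"]):
                for name in sa:
                    assert not np.array_equal(sa[name], sb[name])
            # decoded global model identical: same digest
            assert ra["weights_digest"] == rb["weights_digest"]

    def test_server_view_is_integer_only(self, tiny, codec):
        sc = FederationScenario(**tiny, crypto=CryptoConfig(codec=codec))
        h = run_federation(sc, "shefl", record_server_view=True)
        view = h.rounds[0]["transcript"]["server_view"]
        for sub in view["submissions"]:
            for arr in sub.values():
                assert np.issubdtype(arr.dtype, np.integer)
        for arr in view["aggregate"].values():
            assert np.issubdtype(arr.dtype, np.integer)
            assert int(np.abs(arr).max()) < 2**63

    def test_unknown_mode_rejected(self, tiny):
        with pytest.raises(ValueError):
            run_federation(FederationScenario(**tiny), "secure-ish")
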