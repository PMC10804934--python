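"""Federated training rounds: local epochs, encrypted FedAvg, baselines.

One round of the secure protocol:

1. every site runs one local epoch (round = epoch) from the current global
   weights;
2. each site multiplies its post-epoch parameters by its public FedAvg
   coefficient ``c_k`` in real arithmetic, fixed-point encodes them, and splits
   every tensor into one additive share per site (``encrypt_update``);
3. each site sums the shares it received from all sites modulo Q
   (``holder_combine``) and submits the masked result;
4. the central server adds submissions as plain 64-bit integers — it holds
   neither the modulus nor the precision, and by the modulus invariant the sum
   cannot overflow (``server_aggregate``);
5. every client reduces the aggregate modulo Q, applies the signed lift and
   the fixed-point decode, recovering the FedAvg-weighted mean of the site
   updates up to fixed-point rounding (``decrypt_global``).

The plaintext-FL baseline runs the same schedule with a float FedAvg; the
local baseline trains each site independently.  With identical seeds the
encrypted and plaintext runs agree to within ``N * 10**-p`` per parameter.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np

from . import synthetic_data as synth
from .crypto_ring import (
    FixedPointCodec,
    RingTensor,
    decode,
    encode,
    reduce_mod,
    ring_tensor_to_bytes,
)
from .nn import Adam
from .sharing import make_shares
from .tasks import (
    ClfTrainConfig,
    MLPConfig,
    SegTrainConfig,
    UNetConfig,
    augment_volume,
    balance_by_undersampling,
    build_mlp,
    build_unet,
    normalize_volume,
    one_hot_mask,
    patient_score,
)

__all__ = [
    "CryptoConfig",
    "FederationScenario",
    "ModelUpdate",
    "EncryptedSubmission",
    "FederationHistory",
    "local_train_round",
    "encrypt_update",
    "holder_combine",
    "server_aggregate",
    "decrypt_global",
    "run_federation",
]

_I64_MAX = 2**63


@dataclass(frozen=True)
class CryptoConfig:
    codec: FixedPointCodec
    mask_seed: int = 0  # seeds the share masks, independent of the data seed


@dataclass(frozen=True)
class FederationScenario:
    """Everything needed to reproduce a multi-site run."""

    task: str  # "feature-classification" | "phantom-segmentation"
    n_sites: int = 3
    rounds: int = 3
    seed: int = 0
    crypto: CryptoConfig | None = None
    fedavg_weights: str = "uniform"  # or "size-proportional"
    model_config: object = None  # MLPConfig | UNetConfig; task default if None
    train_config: object = None  # ClfTrainConfig | SegTrainConfig
    data_config: object = None  # FeatureBagConfig | PhantomConfig

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.task not in ("feature-classification", "phantom-segmentation"):
            raise ValueError(f"unknown task: {self.task}")
        if self.crypto is not None:
            if self.n_sites > self.crypto.codec.modulus.max_parties:
                raise ValueError(
                    "n_sites exceeds the modulus max_parties sum bound"
                )
        if self.fedavg_weights not in ("uniform", "size-proportional"):
            raise ValueError(f"unknown weighting: {self.fedavg_weights}")

    def resolved_model_config(self):
        if self.model_config is not None:
            return self.model_config
        data = self.resolved_data_config()
        if self.task == "feature-classification":
            widths = list(MLPConfig().widths)
            widths[0] = data.dim  # input width follows the feature dimension
            return MLPConfig(widths=tuple(widths))
        return UNetConfig(in_channels=data.channels, spatial=data.shape)

    def resolved_train_config(self):
        if self.train_config is not None:
            return self.train_config
        return (
            ClfTrainConfig()
            if self.task == "feature-classification"
            else SegTrainConfig()
        )

    def resolved_data_config(self):
        if self.data_config is not None:
            return self.data_config
        return (
            synth.FeatureBagConfig()
            if self.task == "feature-classification"
            else synth.PhantomConfig()
        )


@dataclass
class ModelUpdate:
    parameters: dict[str, np.ndarray]
    site_id: int
    round_index: int
    sample_count: int


@dataclass
class EncryptedSubmission:
    """One holder's masked contribution: per-parameter modular share sums."""

    holder_id: int
    masked: dict[str, RingTensor]


@dataclass
class FederationHistory:
    mode: str
    rounds: list = field(default_factory=list)

    def final_metric(self):
        return self.rounds[-1]["metric"]


# ---------------------------------------------------------------------------
# Local training
# ---------------------------------------------------------------------------


def _build_model(scenario: FederationScenario):
    cfg = scenario.resolved_model_config()
    if scenario.task == "feature-classification":
        return build_mlp(cfg, seed=scenario.seed)
    return build_unet(cfg, seed=scenario.seed)


def _train_epoch_features(model, site_data, cfg: ClfTrainConfig, rng, opt):
    n, t, d = site_data.features.shape
    x = site_data.features.reshape(n * t, d)
    y = np.repeat(site_data.labels, t)  # weak labels: tiles inherit patient label
    if cfg.balance and len(np.unique(y)) > 1:
        x, y = balance_by_undersampling(x, y, seed=rng.integers(2**31))
    order = rng.permutation(len(y))
    x, y = x[order], y[order]
    params = model.parameters()
    losses = []
    for start in range(0, len(y), cfg.batch_size):
        xb, yb = x[start:start + cfg.batch_size], y[start:start + cfg.batch_size]
        loss, grads = model.loss_and_grads(xb, yb)
        opt.step(params, grads)
        losses.append(loss)
    return float(np.mean(losses))


def _train_epoch_phantom(model, site_data, cfg: SegTrainConfig, rng, opt):
    params = model.parameters()
    order = rng.permutation(site_data.n_patients)
    losses = []
    for i in order:
        vol = normalize_volume(site_data.volumes[i])
        mask = site_data.masks[i]
        if cfg.use_augmentation:
            vol, mask = augment_volume(
                vol, mask, cfg.augment, seed=rng.integers(2**31)
            )
        target = one_hot_mask(np.asarray(mask), model.out_classes)
        loss, grads = model.loss_and_grads(vol[None], target)
        opt.step(params, grads)
        losses.append(loss)
    return float(np.mean(losses))


def local_train_round(
    weights: dict[str, np.ndarray],
    site_data,
    scenario: FederationScenario,
    site_id: int,
    round_index: int,
    model=None,
    optimizer=None,
) -> ModelUpdate:
    """One complete local epoch of Adam from the given weights.

    Deterministic given (scenario seed, site, round).  Each site's Adam
    moment estimates persist across rounds when the caller passes the same
    ``optimizer`` back in (the site keeps one optimizer alive for the whole
    collaboration; the protocol only swaps the weights).  Returns the full
    post-epoch parameter set.
    """
    if site_data.n_patients == 0:
        raise ValueError(f"site {site_id} has an empty dataset")
    if model is None:
        model = _build_model(scenario)
    model.set_parameters(weights)
    rng = np.random.default_rng([scenario.seed, 7001, site_id, round_index])
    cfg = scenario.resolved_train_config()
    if optimizer is None:
        optimizer = Adam(lr=cfg.lr)
    if scenario.task == "feature-classification":
        loss = _train_epoch_features(model, site_data, cfg, rng, optimizer)
    else:
        loss = _train_epoch_phantom(model, site_data, cfg, rng, optimizer)
    params = {k: v.copy() for k, v in model.parameters().items()}
    return ModelUpdate(
        parameters=params,
        site_id=site_id,
        round_index=round_index,
        sample_count=site_data.n_patients,
    )


# ---------------------------------------------------------------------------
# Encryption / aggregation / decryption
# ---------------------------------------------------------------------------


def fedavg_coefficients(scenario: FederationScenario, sample_counts) -> np.ndarray:
    if scenario.fedavg_weights == "uniform":
        return np.full(scenario.n_sites, 1.0 / scenario.n_sites)
    counts = np.asarray(sample_counts, dtype=np.float64)
    return counts / counts.sum()


def encrypt_update(
    update: ModelUpdate,
    scenario: FederationScenario,
    coefficient: float,
) -> dict[int, dict[str, RingTensor]]:
    """Scale by the public FedAvg coefficient, encode, and split into shares.

    Returns ``{holder_id: {tensor name: share}}`` — one message per holder.
    Raises OverflowError naming the tensor if a scaled parameter exceeds the
    codec's representable bound.
    """
    crypto = scenario.crypto
    if crypto is None:
        raise ValueError("scenario has no crypto configuration")
    codec = crypto.codec
    out: dict[int, dict[str, RingTensor]] = {
        h: {} for h in range(scenario.n_sites)
    }
    for name, tensor in update.parameters.items():
        scaled = coefficient * tensor
        try:
            secret = encode(scaled, codec)
        except OverflowError as err:
            raise OverflowError(f"parameter {name!r}: {err}") from err
        if not isinstance(secret, RingTensor):  # scalar parameter
            secret = RingTensor(shape=(), values=np.asarray([secret]))
        if scenario.n_sites == 1:
            # degenerate confederation: the site holds its own encoding
            out[0][name] = secret
            continue
        shares = make_shares(
            secret,
            scenario.n_sites,
            codec.modulus,
            rng_seed=[
                crypto.mask_seed,
                8009,
                update.site_id,
                update.round_index,
                _name_tag(name),
            ],
        )
        for h in range(scenario.n_sites):
            out[h][name] = shares.shares[h]
    return out


def _name_tag(name: str) -> int:
    return int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "big")


def holder_combine(
    holder_id: int,
    received: dict[int, dict[str, RingTensor]],
    scenario: FederationScenario,
) -> EncryptedSubmission:
    """Sum, per parameter and modulo Q, the shares this holder received."""
    if set(received) != set(range(scenario.n_sites)):
        missing = set(range(scenario.n_sites)) - set(received)
        raise ValueError(f"holder {holder_id} missing senders: {sorted(missing)}")
    Q = scenario.crypto.codec.modulus.Q
    names = list(next(iter(received.values())).keys())
    masked: dict[str, RingTensor] = {}
    for name in names:
        acc = np.zeros_like(received[0][name].values)
        for sender in received:
            acc = np.mod(acc + received[sender][name].values, Q)
        masked[name] = RingTensor(shape=received[0][name].shape, values=acc)
    return EncryptedSubmission(holder_id=holder_id, masked=masked)


def server_aggregate(
    submissions: list[EncryptedSubmission],
) -> dict[str, np.ndarray]:
    """Plain integer addition of the masked submissions.

    The server holds neither Q nor the precision and sees only integers; the
    modulus invariant guarantees the sum fits a signed 64-bit integer, which
    is asserted, not assumed.
    """
    names = list(submissions[0].masked.keys())
    out: dict[str, np.ndarray] = {}
    for name in names:
        shape = submissions[0].masked[name].shape
        acc = np.zeros(submissions[0].masked[name].values.shape, dtype=np.int64)
        for sub in submissions:
            if sub.masked[name].shape != shape:
                raise ValueError(f"shape mismatch across submissions for {name!r}")
            vals = sub.masked[name].values
            if acc.size and int(acc.max()) + int(vals.max()) >= _I64_MAX:
                raise OverflowError("server-side sum would exceed 2**63")
            acc = acc + vals
        out[name] = acc.reshape(shape) if shape else acc
    return out


def decrypt_global(
    aggregate: dict[str, np.ndarray], codec: FixedPointCodec
) -> dict[str, np.ndarray]:
    """Client-side: reduce mod Q, signed-lift, divide by the scale."""
    out = {}
    for name, vals in aggregate.items():
        reduced = reduce_mod(np.asarray(vals).ravel(), codec.modulus)
        rt = RingTensor(shape=np.asarray(vals).shape, values=reduced)
        out[name] = decode(rt, codec)
    return out


# ---------------------------------------------------------------------------
# Evaluation of a weight set on a held-out site
# ---------------------------------------------------------------------------


def evaluate_weights(
    weights: dict[str, np.ndarray], test_data, scenario: FederationScenario
) -> float:
    """Held-out metric: patient-level AUROC (features) or mean Dice (phantom)."""
    from .evaluation import auroc, dice_score

    model = _build_model(scenario)
    model.set_parameters(weights)
    if scenario.task == "feature-classification":
        scores = []
        for bag in test_data.features:
            probs = model.predict_proba(bag)[:, 1]
            scores.append(patient_score(probs))
        return auroc(np.asarray(scores), test_data.labels)
    dices = []
    for vol, mask in zip(test_data.volumes, test_data.masks):
        p = model.predict_proba(normalize_volume(vol)[None])
        pred = p[0].argmax(axis=0)
        dices.append(dice_score(pred > 0, np.asarray(mask) > 0))
    return float(np.mean(dices))


# ---------------------------------------------------------------------------
# Full runs
# ---------------------------------------------------------------------------


def _weights_digest(weights: dict[str, np.ndarray]) -> str:
    h = hashlib.sha256()
    for name in sorted(weights):
        h.update(name.encode())
        h.update(np.ascontiguousarray(weights[name], dtype=np.float64).tobytes())
    return h.hexdigest()


def run_federation(
    scenario: FederationScenario,
    mode: str,
    site_datasets: list | None = None,
    test_data=None,
    record_server_view: bool = False,
    record_weights: bool = False,
    eval_every: int = 1,
) -> FederationHistory:
    """Run the configured schedule in ``local``, ``fl`` or ``shefl`` mode.

    ``local`` trains each site independently and reports per-site metrics;
    ``fl`` averages plaintext parameters; ``shefl`` runs the encrypted
    aggregation.  Datasets default to the scenario's synthetic generators
    (sites 0..n-1 for training, site n held out for testing).
    """
    if mode not in ("local", "fl", "shefl"):
        raise ValueError(f"unknown mode: {mode}")
    if mode == "shefl" and scenario.crypto is None:
        raise ValueError("shefl mode requires a crypto configuration")
    if site_datasets is None or test_data is None:
        data = synth.partition_scenario(
            scenario.resolved_data_config(),
            scenario.n_sites,
            scenario.seed,
            task=scenario.task,
        )
        site_datasets = site_datasets or data.train_sites
        test_data = test_data if test_data is not None else data.test_site
    if len(site_datasets) != scenario.n_sites:
        raise ValueError("number of datasets does not match n_sites")

    if mode == "local":
        return _run_local(scenario, site_datasets, test_data)

    model = _build_model(scenario)
    weights = {k: v.copy() for k, v in model.parameters().items()}
    train_cfg = scenario.resolved_train_config()
    optimizers = {s: Adam(lr=train_cfg.lr) for s in range(scenario.n_sites)}
    history = FederationHistory(mode=mode)
    for r in range(scenario.rounds):
        updates = []
        for s, ds in enumerate(site_datasets):
            try:
                updates.append(
                    local_train_round(
                        weights, ds, scenario, s, r,
                        model=model, optimizer=optimizers[s],
                    )
                )
            except Exception as err:
                raise RuntimeError(f"round {r}, site {s}: {err}") from err
        coeffs = fedavg_coefficients(scenario, [u.sample_count for u in updates])
        entry = {"round": r}
        if mode == "fl":
            weights = {
                name: sum(
                    c * u.parameters[name] for c, u in zip(coeffs, updates)
                )
                for name in weights
            }
        else:
            weights, transcript = _shefl_aggregate(
                scenario, updates, coeffs, record_server_view
            )
            entry["transcript"] = transcript
        entry["weights_digest"] = _weights_digest(weights)
        if (r + 1) % eval_every == 0 or r == scenario.rounds - 1:
            entry["metric"] = evaluate_weights(weights, test_data, scenario)
        if record_weights:
            entry["weights"] = {k: v.copy() for k, v in weights.items()}
        history.rounds.append(entry)
    return history


def _shefl_aggregate(scenario, updates, coeffs, record_server_view):
    codec = scenario.crypto.codec
    n = scenario.n_sites
    messages = {u.site_id: encrypt_update(u, scenario, c)
                for u, c in zip(updates, coeffs)}
    n_messages, total_bytes = 0, 0
    for sender, per_holder in messages.items():
        for holder, tensors in per_holder.items():
            for name, rt in tensors.items():
                n_messages += 1
                total_bytes += len(
                    ring_tensor_to_bytes(name, rt, codec.precision, "Q0")
                )
    submissions = [
        holder_combine(h, {s: messages[s][h] for s in messages}, scenario)
        for h in range(n)
    ]
    aggregate = server_aggregate(submissions)
    weights = decrypt_global(aggregate, codec)
    # side-by-side correctness check: the decoded global must match the
    # plaintext FedAvg of the same updates up to fixed-point rounding
    plaintext_gap = 0.0
    for name in weights:
        fedavg = sum(
            c * u.parameters[name] for c, u in zip(coeffs, updates)
        )
        plaintext_gap = max(
            plaintext_gap, float(np.abs(weights[name] - fedavg).max())
        )
    transcript = {
        "n_messages": n_messages,
        "total_bytes": total_bytes,
        "plaintext_gap": plaintext_gap,
    }
    if record_server_view:
        transcript["server_view"] = {
            "submissions": [
                {name: rt.values.copy() for name, rt in sub.masked.items()}
                for sub in submissions
            ],
            "aggregate": {k: v.copy() for k, v in aggregate.items()},
        }
    return weights, transcript


def _run_local(scenario, site_datasets, test_data):
    history = FederationHistory(mode="local")
    per_site_weights = []
    model = _build_model(scenario)
    init = {k: v.copy() for k, v in model.parameters().items()}
    train_cfg = scenario.resolved_train_config()
    for s, ds in enumerate(site_datasets):
        weights = {k: v.copy() for k, v in init.items()}
        opt = Adam(lr=train_cfg.lr)
        for r in range(scenario.rounds):
            update = local_train_round(
                weights, ds, scenario, s, r, model=model, optimizer=opt
            )
            weights = update.parameters
        per_site_weights.append(weights)
    metrics = [
        evaluate_weights(w, test_data, scenario) for w in per_site_weights
    ]
    history.rounds.append(
        {
            "round": scenario.rounds - 1,
            "metric": metrics,
            "weights_digest": [_weights_digest(w) for w in per_site_weights],
        }
    )
    return history
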