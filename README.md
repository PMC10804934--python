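# shefl — somewhat-homomorphically-encrypted federated learning

Multi-centre medical-imaging AI runs into a wall: the data needed to train
good models is scattered across hospitals that cannot share it. Federated
learning (FL) keeps the data local and shares only model weights — but a
curious aggregation server can run a *gradient-inversion attack* on the
plaintext weight updates and reconstruct the training images. `shefl`
implements the standard countermeasure for the honest-but-curious-server
threat model: **additive secret sharing over a prime ring (SPDZ-style,
without zero-knowledge proofs), applied only to the FedAvg weight-aggregation
step**, so that the server only ever sees uniformly random residues while the
clients recover a global model that is identical to plaintext FedAvg up to
fixed-point rounding.

The package is a self-contained laboratory for this protocol. It contains

- the **fixed-point prime-ring codec**: a real value `x` is encoded as
  `round(x · 10^p) mod Q` for a public prime `Q`; with decimal precision
  `p = 13` the round-trip is lossless relative to single-precision inputs
  (`shefl.crypto_ring`);
- **additive secret sharing**: `x` is split into `N` shares
  `x_1, …, x_{N-1} ~ Uniform[0, Q)` and
  `x_N = (x − x_1 − … − x_{N−1}) mod Q`, reconstructed as
  `x = (x_1 + … + x_N) mod Q`; shares support homomorphic addition and
  public-scalar multiplication (`shefl.sharing`);
- the **federated round protocol**: local epoch → FedAvg pre-scaling and
  encryption → share distribution → per-holder modular combination →
  server-side *plain 64-bit integer* addition (the server holds neither `Q`
  nor `p`) → client-side decryption, plus plaintext-FL and local-only
  baselines (`shefl.federation`);
- the two **task recipes** — 3-D U-Net phantom segmentation with Dice loss
  and a four-layer fully connected classifier on 512-d tile-feature bags with
  weak patient labels — built on a small NumPy layer stack with exact
  hand-verified gradients (`shefl.tasks`, `shefl.nn`);
- **synthetic multi-site data generators** with controlled heterogeneity
  (site gains/offsets, channel-contrast jitter, batch-effect feature offsets,
  prevalence shifts) and a held-out test site (`shefl.synthetic_data`);
- the **gradient-inversion attack** (dummy-input optimization against
  captured gradients, analytic label recovery from final-layer gradient
  signs) and its demonstrated failure against masked shares (`shefl.attack`);
- **evaluation utilities**: Dice, AUROC, 1000-redraw bootstrap spread, and
  Shapiro–Wilk-gated paired tests (`shefl.evaluation`).

## Worked example

```python
import numpy as np
from shefl import FixedPointCodec, encode, decode, generate_modulus
from shefl.federation import FederationScenario, CryptoConfig, run_federation

# the crypto provider picks a 61-bit prime; p = 13 decimal digits
modulus = generate_modulus(bit_length=61, max_parties=4, seed=0)
codec = FixedPointCodec(precision=13, modulus=modulus)
print(encode(2.9874, FixedPointCodec(precision=3, modulus=modulus)))
# -> 2987  (the integer that represents 2.9874 at precision 3)

base = dict(task="feature-classification", n_sites=3, rounds=3, seed=7)
fl = run_federation(FederationScenario(**base), "fl")
she = run_federation(
    FederationScenario(**base, crypto=CryptoConfig(codec=codec, mask_seed=1)),
    "shefl",
)
print(round(fl.final_metric(), 6), round(she.final_metric(), 6))
# -> 0.647321 0.647321   (held-out patient AUROC, identical across modes)
```

The encrypted and plaintext runs produce the same held-out AUROC because the
only difference between them is fixed-point rounding of order `10^-13` per
aggregation.

The same protocol from the shell:

```bash
shefl synth --task features --sites 3 --out data/
shefl simulate --config scenario.json --mode shefl --seed 1 --out runs/shefl
shefl attack --mode plaintext --out attacks/plain --seed 0
shefl eval --runs runs/local --runs runs/fl --runs runs/shefl
```

`shefl attack --mode plaintext` prints, e.g.
`plaintext: PSNR 53.82 dB (random baseline -4.01 dB)` — the captured update
leaks the training patch almost perfectly. `--mode masked` on the same
instance stays at the random baseline: the server-visible share carries no
usable signal.

## Scope

Real patient cohorts, whole-slide-image preprocessing, CKKS/fully
homomorphic encryption, differential privacy, network transport and
malicious-participant defenses are out of scope. See `docs/methods.md` for
the model, parameter and design details.
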