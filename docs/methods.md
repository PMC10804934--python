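# Methods

## Protocol

`shefl` implements secure aggregation for federated averaging under the
honest-but-curious-server threat model: a confederation of mutually trusting
sites trains a shared model; the aggregation server follows the protocol but
tries to learn what it can from the messages it receives. Encryption is
applied *only* to the weight-aggregation step — local backpropagation happens
behind each site's firewall and needs no protection — which is what keeps the
cryptographic overhead negligible relative to training.

One round (round = one local epoch):

1. **Local epoch.** Every site runs one epoch of Adam on its own data,
   starting from the current global weights. Each site keeps a single Adam
   optimizer alive for the whole collaboration; the protocol swaps weights,
   not optimizer state. (Re-initializing the moment estimates every round
   re-introduces warm-up transients each round and measurably destabilizes
   small-data training.)
2. **Scale and encode.** Site `k` multiplies its post-epoch parameters by its
   public FedAvg coefficient `c_k` (uniform `1/N` by default,
   size-proportional `n_k/n` optionally) in real arithmetic, then encodes
   every tensor entry as `round_half_even(c_k w · 10^p) mod Q`. Scaling
   before encoding means the server only ever *adds* — no fixed-point
   multiplication, hence no truncation protocol is needed.
3. **Share.** Each encoded tensor is split into `N` additive shares — the
   first `N−1` i.i.d. uniform on `[0, Q)`, the last the modular complement —
   and one share is sent to each site (including the sender itself). Any
   `N−1` shares are exactly uniform: the masking leaks nothing. (Shares are
   drawn on the closed-below range `[0, Q)` rather than the open interval
   `(0, Q)`; uniform residues are the natural choice and the difference is
   immaterial to both correctness and masking.)
4. **Combine.** Each site sums the shares it received from all sites mod `Q`
   and submits the masked result to the server.
5. **Aggregate.** The server adds the `N` submissions as plain signed 64-bit
   integers. The server holds neither `Q` nor `p`; the modulus invariant
   `max_parties · (Q − 1) < 2^63` guarantees the plain sum cannot overflow
   (asserted at run time, not assumed).
6. **Decrypt.** Every client reduces the aggregate mod `Q`, lifts residues
   above `(Q−1)/2` to negatives, and divides by `10^p`. The result is the
   FedAvg-weighted mean of the site updates up to at most `N · 0.5 · 10^−p`
   absolute error per parameter.

Whole post-epoch parameter vectors are shared rather than weight deltas; the
two are equivalent under FedAvg and sharing parameters keeps the server
stateless. Transport is in-process message passing; messages use a wire form
of a JSON header plus little-endian signed 64-bit payloads, matching the
constraint that encrypted weights must travel as 64-bit integers.

### Correctness and its limits

Within one aggregation, the decoded global model differs from the plaintext
FedAvg of the same updates by at most one fixed-point rounding per site, i.e.
`N · 0.5 · 10^−p` — at `p = 13`, of order `10^−13`. Every SHEFL round records
this side-by-side gap in its transcript and the test suite asserts it.

Across *rounds*, the comparison between a full SHEFL run and a full
plaintext-FL run is not bounded by that number: a local training epoch is not
1-Lipschitz, so the `10^−13` perturbation introduced at round `r` is amplified
by the optimization at round `r+1` (measured drift at default conditions:
~1.5e-13 after round 1, a few times `10^−12` by round 3). The drift stays far
below anything a metric can resolve — final held-out metrics of the two runs
agree exactly in practice — but per-round *weight* agreement between two
independent runs holds strictly only at round 1 and per aggregation.

### Crypto parameters

| parameter | default | why |
| --- | --- | --- |
| precision `p` | 13 decimal digits | round-trip error `≤ 0.5·10^−13` is below single-precision resolution for values in the weight range — effectively lossless |
| modulus bits | 61 | largest size such that 4 parties satisfy the 64-bit sum bound |
| max parties | 4 | `4 · (2^61 − 1) < 2^63` |
| scaling base | 10 | decimal fixed point (`2.9874 → 2987` at `p = 3`) |
| rounding | half-to-even | unbiased on the representable grid |
| negatives | residue in `[0, Q)`, signed lift at `(Q−1)/2` | standard balanced representation |

Primality uses `sympy.isprime`, deterministic below `2^64`. The
representable magnitude bound `|x| ≤ (Q−1)/(2·10^p)` (~115 at defaults) is
enforced at encode time; exceeding it raises an overflow error naming the
offending tensor. The "crypto provider" is a deterministic parameter
authority: it generates `Q` from a seed and never sees data or shares. All
sites share one key, as appropriate when every participant receives the final
model anyway; key distribution is out of scope.

Share randomness is counter-based: each (site, round, tensor) derives its
stream from `(mask_seed, site, round, hash(tensor name))`, so runs are
reproducible and the mask seed can be varied independently of the data seed —
which is how the server-view secrecy property is tested (two mask seeds: every
server-visible integer changes, the decoded model does not).

## Tasks

**Phantom segmentation.** 4-channel volumes are normalized per channel (clip
above the 99th percentile, shift to zero minimum, divide by the maximum;
constant input maps to zeros), optionally augmented (center-biased crop; two
independent flips with probability 0.4 applied identically to the mask;
power-law intensity rescale `I ← g·I^γ`, `g, γ ~ U(0.8, 1.2)`; additive white
Gaussian noise `σ = 0.03` per channel), and fed to a 3-D U-Net trained with
soft Dice loss over the foreground classes (`ε = 10^−5`, mean over
non-background classes) using Adam. The U-Net follows the
contract/expand-with-skip-concatenation topology: each block is two 3×3×3
convolutions, each followed by ReLU and a normalization layer; 2×2×2 max
pooling between contraction levels; nearest-neighbour upsampling and skip
concatenation on the way up; a 1×1×1 convolution to the class channels and a
channel softmax. The first convolution maps the input channels directly to
the base width; widths double per contraction level. Normalization uses
instance statistics, which is what batch normalization degenerates to at the
single-volume batch size used here. Reference scale is 4 levels / 48 base
channels / 128³ inputs at Adam lr `10^−4` for 100 epochs; the package's desk
scale is 2 levels / 4 base channels / 16³, which trains in seconds per epoch
while exercising the identical code path.

**Feature-bag classification.** Each patient is a bag of 512-d tile feature
vectors; every tile inherits its patient's binary label (weak labels). Tiles
are class-balanced by random undersampling to the minority count, then a
four-layer fully connected network (512×256, 256×256, 256×128, 128×2, ReLU
between layers, He initialization) is trained with cross-entropy, Adam at lr
`4·10^−5`, batches of 124, reference schedule 100 epochs, 150 tiles per
patient. The four-layer stack has 230,274 trainable parameters
(`Σ(in·out + out)`); pipelines of this kind are sometimes reported with
492,930 parameters, which corresponds to an additional 512×512 input layer —
this package implements the four layers as specified. Patient-level scores
are the mean of the tiles' positive-class probabilities (the simplest
order-invariant pooling; the tile→patient rule is otherwise a free choice).

All neural components (dense/conv layers, instance norm, pooling,
upsampling, losses, Adam, He init) are a small NumPy layer stack inside the
package (`shefl.nn`), float64 throughout, with gradients verified against
central finite differences to `10^−6` relative in the test suite. Float64 and
full determinism are what make the encrypted-vs-plaintext comparison
meaningful at the `10^−13` level.

## Synthetic data

The generators are pure functions of (config, site_id, seed); a held-out test
site uses `site_id = n_train_sites` and therefore draws parameters disjoint
from every training site.

**Phantom sites** contain one ellipsoidal lesion per patient — a core inside
a rim on constant background, three mask classes — with per-site intensity
gain (0.7–1.3), offset (±0.1), noise level, and per-channel contrast jitter
that rescales the class contrasts. Lesion radii default to 4–6 voxels in a
16³ volume with `core_fraction = 0.7`: at desk scale the foreground must
occupy a workable fraction of the volume (≈13%), because the soft-Dice
gradient for a class with near-zero predicted overlap vanishes as
`ε/denominator²` and a sub-1% class regularly collapses into that degenerate
basin.

**Feature sites** draw patient labels from a site-jittered prevalence, then
tiles `~ N(site_offset + label·δ·1_active, I)` with `δ = 0.12` on 32 of 512
dimensions and site offset vectors of scale 0.3. Constant per-site offsets
shift every tile alike and therefore cannot change a rank metric on a single
test site; what creates the single-site/pooled gap is estimation noise —
training sites are small (8 patients by default) while the held-out cohort is
larger (60), mirroring the small-clinic / large-trial-cohort asymmetry of
multi-site studies. Defaults were calibrated once so that single-site models
land around AUROC 0.8–0.9 on the held-out cohort with the pooled/federated
model above them, and then frozen.

What the generators do *not* emulate: MRI physics, texture, partial-volume
effects, stain variation, label noise, or realistic class geometry. Passing
the ordering and dichotomy tests therefore demonstrates that the *protocol
and pipeline* behave correctly under controlled heterogeneity, not that the
models would reach any particular performance on real cohorts.

## Gradient-inversion attack

`capture_update` records the exact task-loss gradients for a batch — what a
malicious server sees in plaintext FL for a site doing a single-sample
update. The label is recovered analytically from the final layer: for softmax
cross-entropy at batch 1 the bias gradient is `p − onehot`, whose unique
negative entry is the true class (the weight-row Gram-sign rule covers
bias-free heads); ambiguity (batch > 1) falls back to joint optimization over
candidate labels. The input is then reconstructed by minimizing the squared
L2 distance between the dummy input's gradients and the captured ones with
L-BFGS over the flattened input. The gradient of the match loss with respect
to the dummy input — a vector–Jacobian product through the weight gradient —
is computed by a central finite difference of the *input gradient* along the
residual direction in weight space (two extra backward passes per iteration;
verified against brute-force finite differences to `10^−10`). The match loss
is normalized by the captured gradient's energy so termination tolerances are
scale-invariant; the dummy input initializes from a seeded standard normal.

The demonstration network is two 3×3 convolutions plus a dense softmax head
on an 8×8 phantom slice, with **sigmoid** activations: with ReLU the
gradient-match landscape fragments into dead-unit regions and inversion from
a random start stalls in local minima (recovery succeeds only from near the
truth), while with smooth activations a single L-BFGS run drives the match
loss to ~`10^−8` and reconstructs the patch at 50–80 dB PSNR. This matches
the folklore that gradient inversion is easiest on smooth networks; ReLU
remains available for training use.

Reported metrics: MSE and PSNR against the true patch (peak = the original's
dynamic range), against a baseline defined as the *best* PSNR among 16 random
images drawn from the dummy-init distribution. An attack that learned nothing
scores at or below this best-of-K baseline; the plaintext attack exceeds it
by tens of dB, and the identical pipeline pointed at one masked share — the
only thing the server sees under SHEFL, lifted to reals as-is — stays at the
baseline. "At the baseline" is asserted as `PSNR ≤ baseline + 1 dB`; values
slightly *below* the baseline are expected, since the baseline is a maximum
over draws.

## Evaluation and statistics

- Dice similarity `2|A∩B|/(|A|+|B|)` over merged foreground per patient; two
  empty masks score 1 by convention.
- AUROC via midrank-tied Mann–Whitney (scikit-learn), brute-force
  pair-counting oracle in the tests.
- Bootstrap spread: patients resampled with replacement, 1000 redraws by
  default, mean ± sd of the metric across redraws (`ddof = 1`); single-class
  redraws are rejected and redrawn.
- Paired comparisons: Shapiro–Wilk on the paired differences at α = 0.05
  gates a two-tailed paired t-test (normal) vs Wilcoxon signed-rank
  (otherwise); all-zero differences short-circuit to a flagged degenerate
  result with p = 1. The gate is applied to the differences, the quantity the
  tests actually assume normal. p ≤ 0.05 is reported as significant; no
  multiple-testing correction is applied.

## Desk-scale experiment sizes

The package's experiments are sized to run on one CPU core in minutes, as the
package's own study conditions:

- protocol-equivalence runs: 3 sites × 3 rounds on the feature task at full
  model width (230k parameters per update, encrypted and shared every round);
- ordering experiments (feature): 3 training sites of 8 patients × 150 tiles,
  60-patient held-out cohort, 30 rounds at classifier lr `2·10^−4` (a
  desk-scale schedule reaching the same training state as the reference lr
  over many more epochs);
- ordering experiments (phantom): 3 training sites of 6 patients at 16³,
  held-out site of 12 patients, U-Net at 2 levels / 4 base channels, 40
  rounds at lr `3·10^−3` without augmentation (at this data volume the
  augmentation noise dominates the signal and stalls the Dice plateau;
  at reference scale augmentation is part of the recipe);
- attack instances: 8×8 patches, 300 L-BFGS iterations, 5 paired seeds.

## Scenario configuration schema (CLI)

`shefl simulate --config scenario.yaml` accepts a YAML/JSON mapping:

| key | type / values | default | meaning |
| --- | --- | --- | --- |
| `task` | `feature-classification` \| `phantom-segmentation` | features | which recipe to run |
| `n_sites` | int ≥ 1 | 3 | training sites (site `n_sites` is held out) |
| `rounds` | int ≥ 1 | 3 | federated rounds; one round = one local epoch |
| `fedavg_weights` | `uniform` \| `size-proportional` | uniform | FedAvg coefficients |
| `crypto.bit_length` | 4–62 | 61 | modulus size in bits |
| `crypto.precision` | int ≥ 0 | 13 | decimal fixed-point digits `p` |
| `crypto.max_parties` | int ≥ 2 | 4 | sum-bound parameter of the modulus |
| `crypto.modulus_seed` | int | 0 | seed for prime generation |
| `crypto.mask_seed` | int | `--seed` | seed for share masks (independent of data) |
| `data.*` | fields of `FeatureBagConfig` / `PhantomConfig` | module defaults | generator parameters |

`--seed` drives data generation and training; `--mode {local,fl,shefl}`
selects the setting. Model topology defaults follow the data configuration
(input width = feature dimension; U-Net input channels and spatial size from
the phantom config) and can be overridden in the library API.

## Known limitations

- Security is argued for the honest-but-curious server only: no MACs or
  zero-knowledge proofs, no defense against malicious participants, no
  dropout handling, no real transport.
- The per-round two-run weight bound discussed under *Correctness* holds at
  the aggregation step; independent-run drift grows with training depth.
- Gradient inversion at batch sizes > 1, against batch-norm statistics, or
  with image priors is out of scope.
- The synthetic generators are deliberately minimal; absolute metric values
  have no clinical meaning.
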