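# gcfe — Gershgorin-circle feature extraction for biomedical time series

`gcfe` turns an epoch of a biomedical recording (EEG, extracellular spikes)
into a compact spectral-style feature vector without ever computing an
eigendecomposition. It is aimed at people building classifiers over
single-channel time series who need graph-based features that stay cheap as
epochs get long.

## The method

1. **Normalize** the recording to [0, 1] against its whole-recording
   extrema and cut it into non-overlapping epochs of N samples.
2. **Visibility graph.** Each sample becomes a node; samples *i* < *j* are
   linked when every intermediate sample lies strictly below the chord
   joining (i, q\_i) and (j, q\_j). Each edge carries the weight

   w(i, j) = |q\_i − q\_j| / |i − j| + 10⁻⁸,

   the absolute slope between its endpoints (time in sample units) plus an
   epsilon that keeps flat segments at nonzero weight. The
   *dual-perspective* variant (WDPVG) unions this graph with the
   visibility graph of the reflected signal.
3. **Modified weighted Laplacian.** L = D − A, where A is the *weighted*
   adjacency and D the diagonal of *unweighted* node degrees. For
   normalized epochs every weight is ≤ 1 + ε, so each diagonal entry
   dominates its row and L is (near-)diagonally dominant.
4. **Gershgorin disks.** By the Gershgorin circle theorem, every
   eigenvalue of L lies in a disk centered at c\_i = L\_ii with radius
   r\_i = Σ\_{j≠i} |L\_ij|. The epoch's feature vector is
   [r\_1 … r\_N, c\_1 … c\_N] — length 2N, computed with row sums only.

The radii measure local slope energy around each sample; the centers are
visibility degrees. A seeded simulator generates multi-unit spike
recordings (cosine-under-Gaussian action potentials, Poisson firing,
band-limited Gaussian noise at a target SNR) and EEG-like surrogates, and
a small 1-D CNN (implemented on numpy) classifies the feature vectors.

## Worked example

The five-sample normalized series Q = [0.6, 0.4, 0.1, 0.5, 0.7]:

```sh
$ printf 'value\n0.6\n0.4\n0.1\n0.5\n0.7\n' > q.csv
$ gcfe extract q.csv --epoch-len 5 --out q_features.csv
$ cat q_features.csv
r1,r2,r3,r4,r5,c1,c2,c3,c4,c5
0.2583333633333331,0.6500000399999992,0.7000000200000001,0.6833333733333333,0.32500003,3.0,4.0,2.0,4.0,3.0
```

Radii ≈ [0.258, 0.650, 0.700, 0.683, 0.325]: node 3 (the valley) has the
largest radius because its two steep adjacent slopes (0.3 and 0.4)
dominate its row. Centers [3, 4, 2, 4, 3] are the node degrees — node 3
sees only its neighbours, while nodes 2 and 4 see four nodes each. The
same numbers are available in Python:

```python
from gcfe import Epoch, extract_features
f = extract_features(Epoch(q=[0.6, 0.4, 0.1, 0.5, 0.7]), "wvg")
f.radii.round(3)    # array([0.258, 0.65 , 0.7  , 0.683, 0.325])
f.centers           # array([3., 4., 2., 4., 3.])
```

An end-to-end run on simulated spike data (simulate → extract → train the
CNN → evaluate on a held-out split):

```sh
$ gcfe demo --snr 10 --n-per-class 100 --seed 0 --out demo10
accuracy=88.333% sensitivity=88.333% specificity=96.111%
```

88.3% of held-out epochs are assigned to the correct unit (or to the
noise class); sensitivity and specificity are macro-averaged one-vs-rest.
At the simulator's noisiest setting (`--snr 2`) the visibility structure
is largely noise-driven and accuracy drops sharply — see
`docs/methods.md` for what the simulator does and does not capture.

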