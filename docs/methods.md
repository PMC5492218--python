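# Methods

## Problem setting

A session is a set of samples assumed to share one concept: here,
7-channel normalized RMS amplitude features (0–5 V) with one of 8 motion
labels. A session sequence carries drift: *drift extent* is the
distributional difference between two sessions, *drift rate* the extent
between adjacent sessions. Classifiers are validated prequentially — the
first session of the validating order initializes the model, every later
sample is scored against its true label *before* it may influence any
update, and accuracy is aggregated per session (RA_i). Ending
performance is summarized by AER (mean RA over the last five sessions,
%) and WMP (mean over the last five sessions of the worst per-class
accuracy, %). Reversing the validating order (last session initializes)
controls for accidental features of the first recording.

## The particle adaptive classifier

**Model.** One binary LS-SVM per unordered class pair over a fixed pool
of representative particles. The LS-SVM dual is the SPD system
(0 1ᵀ; 1 K + C⁻¹I)(b; α) = (0; Y); its solution is recovered from the
Cholesky factor R of H = K + C⁻¹I as b = (1ᵀH⁻¹Y)/(1ᵀH⁻¹1),
α = H⁻¹(Y − b·1), two triangular solves per quantity. Because the model
is full-dense (Cξᵢ = αᵢ at the optimum — every particle keeps a
coefficient), the pool composition fully determines the model.

**Incremental engine.** Inserting, deleting or replacing the particle at
position p edits one row/column of H. The factor is repaired rather than
recomputed: forward substitution gives the new column's upper part u₁,
the pivot is u_pp = √(h_pp − u₁ᵀu₁), the trailing row is
u₂ = (h₂ − U₂ᵀu₁)/u_pp, and the trailing block is corrected by a
rank-one Cholesky downdate (insert) or update (delete) with u₂,
implemented with the standard Givens / hyperbolic rotation sweeps.
Coefficients are then re-solved against the maintained factor. Total
cost O(l²); replacement is one delete followed by one insert at the same
position. A downdated pivot below 1e−12 is treated as loss of positive
definiteness (impossible in exact arithmetic for RBF + C⁻¹I): the
operation raises, and the streaming classifier falls back to batch
retraining of the affected models. sgn(0) → +1 throughout.

**Operation counting.** Scaling claims are checked on a deterministic
operation counter rather than wall clock: each routine adds the dominant
floating-point work it performs (n² per triangular solve, 4m² per
rank-one sweep, l³/3 per dense Cholesky, l²·d per Gram matrix). Fitted
log-log slopes over l ∈ {50, 100, 200, 400} are ≈2 for surgery and ≈2.8
for batch training (the batch exponent sits below 3 because the l² terms
have not vanished at l = 400).

**Initialization.** The pooled training session (class-agnostic) is
clustered into m groups by PAM-style k-medoids on the kernel-space
metric d = √(2 − 2k) (precomputed distance matrix, alternating
assignment/medoid steps, at most 100 iterations, seeded random medoid
initialization); round(p·n) particles are drawn across clusters with
largest-remainder proportional allocation and labeled by their training
labels. A class left without particles is an error: its pairwise models
would be untrainable.

**Streaming update.** Per sample: one-vs-one majority vote (ties to the
lowest class index); every particle's unchanging time tᵢ increments;
the nearest particle minimizes exp(tᵢ/λ)·d(x_N, xᵢ) (ties to the lowest
index), reusing the kernel products already computed for prediction;
replacement happens iff d_Th − exp(t_I/λ)·d(x_N, x_I) > 0 (strict), after
which t_I = 0. Supervised mode restricts the nearest-particle search to
the sample's true class and skips the update entirely on a
misclassification; unsupervised mode uses the predicted label. When the
predicted label differs from the replaced particle's class (unsupervised
only), the particle is deleted from its old class's pairwise models and
appended to the new class's — this preserves the one-vs-one construction
(each particle backs exactly n_classes − 1 models) at the cost of letting
individual pair sizes vary; a class change that would empty a class is
skipped so the ensemble stays trainable. Pool size, and therefore total
ensemble support and per-cycle cost, never change.

**Parameters.** Defaults m = 10, p = 0.10, d_Th = 0.99, λ = 1e5, with
advisory warnings outside the recommended ranges p ∈ [0.10, 0.20],
m ∈ [9, 28], λ ∈ [1e4, 1e6], d_Th ∈ [0.9, 1.1]. d_Th is in units of the
kernel metric (range [0, √2)): d_Th = 0.99 admits samples with k > 0.51
to their nearest particle. λ is in units of processed samples; since the
reference value 1e5 corresponds to ≈25 sessions of 4000 samples, the
scaled experiments below use λ = 1e4 ≈ 25 sessions of 400 samples —
the same time constant in session units. (C, γ) are fixed by stratified
n-fold cross-validation on the initialization session before streaming
and never re-tuned. With d_Th = 0 the zone test never fires and the
classifier degenerates to a frozen model; the attractive-zone inequality
is implemented literally (strict), so no replacement occurs at d_Th = 0.

## Baselines

NSVC is a standard one-vs-one C-SVC (libsvm via scikit-learn, QP
tolerance 1e−3) trained once. ISVC retrains, at every cycle, a C-SVC on
the union of the previous model's support vectors and the new sample
(true label in supervised mode, own prediction in unsupervised mode),
one sample per updating cycle; KKT pruning keeps boundary samples, so
the SV set — and per-cycle cost — grows on drifting streams. CV defaults
follow libsvm practice (C ∈ 2^{−5..15}, γ ∈ 2^{−15..3} in powers of 4,
5 folds); ties prefer the smallest C, then the smallest γ.

## Drift simulator

Q_n = {E_(k/n)}, k = 0..n, from one base session. At fraction u = k/n
each sample (normalized to [0, 1] internally; the transform's additive
0.2 term is only range-closed on the unit scale) passes through a DC
noise step x̃_j = (x_j + 0.25u)/(1 + 0.25u) (impedance change/fatigue)
and adjacent-channel fusion x'_j = x̃_j(1 − 0.5u) + 0.5u·x̃_{j+1} with
channel 7 wrapping to channel 1 (electrode ring shift). At u = 1 this is
exactly 0.4x_j + 0.4x_{j+1} + 0.2. Labels are preserved (real drift).
Sessions with equal k/n are identical across n; extent is monotone in k
and the adjacent-session rate scales as 1/n.

## Synthetic sessions

Each motion's mean activation template is a contiguous 2-channel block
on the 7-electrode ring (motion 8 is an all-channel co-contraction),
with alternating strong/moderate amplitudes (0.85/0.70) distinguishing
neighbouring blocks; samples add Gaussian noise (sd 0.10 on the unit
scale) truncated by clipping to [0, 1], and an amplitude gate discards
samples whose channel mean does not exceed 20% of the maximum voluntary
contraction (strict inequality, as at acquisition). Contiguous blocks
were chosen deliberately: muscle synergies recruit anatomically adjacent
muscles, and a contiguous block survives the adjacent-channel fusion
drift as a (shifted) block, so classes remain clustered — the cluster
and smoothness assumptions the unsupervised updating relies on — while
their territories move far enough that a frozen classifier fails.
(Alternating-channel templates, by contrast, average toward uniform
under fusion and make the task genuinely unlearnable mid-drift.) The
generator emulates class-clustered, bounded, amplitude-gated feature
distributions with controllable overlap; it does not model transient
dynamics, inter-subject variability, within-session autocorrelation or
electrode-specific noise spectra, so results on it speak to classifier
mechanics under drift, not to absolute accuracy on recorded muscle
signals.

## Problem sizes and experimental choices

The package's standard experiment sizes are chosen for a single CPU:
sessions of 400 samples (50 per class) rather than 4000, drift families
n ∈ {8, 32, 128}, ten seeds, λ = 1e4 (see above). Under these
conditions the frozen baseline's session accuracy falls from ≈1.0 to
≈0.2 across the drift family (Spearman ρ ≈ −0.95 against session
position) and unsupervised PAC tracks the n = 128 sequence at ≈1.0.

The degradation ordering across adaptation strategies (uISVC ≥ uPAC ≥
sPAC ≥ sISVC, in final-session degradation) is a statement about drift
rates near or beyond the unsupervised trackers' thresholds. At these
scaled sizes every adaptive classifier adapts completely for n ≥ 2
(degradations within 0.001 of zero, so the ordering would be decided by
ties), and the discriminating regime is the abrupt-shift sequence n = 1
(one jump to maximum extent): there the self-labeled ISVC is poisoned by
its own mispredictions, unsupervised PAC fails more gracefully, and the
supervised variants recover — so the ordering is evaluated at n = 1.

Known limitations: unsupervised PAC depends on the cluster assumption —
when class overlap grows (or drift renders classes inseparable), wrong
predicted labels enter the pool and corruption can cascade to complete
failure, which is the documented failure mode of too-permissive
(d_Th, λ); the incremental engine's re-solve step makes deletion O(l²)
rather than O((l−p)²); and cycle-time measurements are recorded for
inspection but never asserted, being hardware-dependent.
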