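# trustwalk

Quantum and Markov random-walk models of how a person's judgement of an AI
system's reliability evolves over repeated interactions, together with a
synthetic Wizard-of-Oz experiment generator and a simplified event-related
potential (ERP) stage for the neural response to AI disagreement.

The package is for computational cognitive scientists who want to compare
the two model families on rating data from human–AI interaction studies —
and, because such data are rarely released, to generate realistic synthetic
sessions (trial logs, per-block reliability ratings, feedback-locked EEG
epochs) on which the full analysis runs end to end.

## The models

Reliability is judged on a discrete scale of *n* = 11 levels,
x ∈ {0, …, 10}; slider ratings on 0–100 are binned onto it in 9-point bins
(ratings ≥ 90 map to the top level).

**Markov (birth–death) walk.** The judgement occupies a definite level at
every instant and hops only to neighbours. With up-rate β⁺ and down-rate β⁻
(self-intensity α = β⁺ + β⁻), the tridiagonal intensity matrix K drives the
Kolmogorov forward equation

    dφ/dt = Kφ,   φ(t) = e^{tK} φ(0),   P_t(R = i) = φ_i(t).

K is column-oriented (column j holds the flow out of level j) with
reflecting boundaries, so every column sums to zero and probability is
conserved exactly. Defaults: β⁺ = 0.6, β⁻ = 0.4 (α = 1).

**Quantum walk.** Between measurements the judgement is a superposition
ψ over all levels, evolved unitarily by a real symmetric Hamiltonian

    dψ/dt = −iHψ,   ψ(t) = e^{−itH} ψ(0),   Q_t(R = i) = |ψ_i(t)|².

H has a linear diagonal potential μ_x = 0.05·x (drift toward high
reliability while the AI keeps agreeing), neighbour diffusion σ² = 0.7, and
a corner coupling H[0, n−1] = H[n−1, 0] = z = 0.2 that lets high
reliability expectations collapse abruptly to the bottom level.

Both models start from either a uniform state or a 7-point symmetric
stencil centred on the participant's mapped post-practice rating, evolve
*continuously* across the session (no collapse between ratings), and are
scored by the RMSE between their expected-state trajectory and the observed
(binned) per-block ratings.

## Worked example

```python
from trustwalk import RatingGeneratorParams, compare_models, generate_rating_trajectory

observations = generate_rating_trajectory(RatingGeneratorParams(seed=12), n_blocks=20)
result = compare_models(observations)
print(f"RMSE markov : {result.rmse_markov:.3f}")
print(f"RMSE quantum: {result.rmse_quantum:.3f}")
```

prints

```
RMSE  markov : 0.821
RMSE  quantum: 1.437
```

Here the synthetic ratings (damped oscillation from 48.9% toward a 75%
asymptote) happen to favour the smoother Markov trajectory; quantum-
generated data favour the quantum model (see the self-recovery tests). Each
RMSE is in units of reliability *levels* on the 11-level scale — 0.82 means
the model's expected state tracks the observed state to within about one
level on average. `result.per_block_error` holds the per-block table behind
both numbers.

More in `examples/`: rating binning and initial-state construction, the
full ERP pipeline recovering the oddball (P3-like) response from synthetic
epochs, and a one-call reproducible run (`run_all`) writing every artifact
of the simulate → compare → erp chain to a directory. The same chain is
scriptable from a shell via the `trustwalk` CLI (`simulate`, `compare`,
`erp`, `run-all`), configured by one sectioned YAML/JSON file.

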