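"""Score the Markov and quantum walks against one synthetic session's
per-block reliability ratings (root mean square error on the 11-level scale)."""

from trustwalk import RatingGeneratorParams, compare_models, generate_rating_trajectory

# Twenty blocks of ratings that oscillate early and settle near 75%,
# starting from a post-practice rating of 48.9%.
observations = generate_rating_trajectory(RatingGeneratorParams(seed=12), n_blocks=20)
print("block ratings (%):", [round(o.raw_rating, 1) for o in observations[1:6]], "...")

# Both models start from the weighted stencil at the mapped post-practice
# rating and evolve continuously; each block's rating is read out at the
# block's last trial (0.1 model time units per trial).
result = compare_models(observations)
print(f"\nRMSE  markov : {result.rmse_markov:.3f}")
print(f"RMSE  quantum: {result.rmse_quantum:.3f}")
print("\nfirst blocks of the error table:")
print(result.per_block_error.head(5).to_string(index=False))
# Lower RMSE = that model's expected-state trajectory tracks the observed
# (binned) ratings more closely over the session.
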