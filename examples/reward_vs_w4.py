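"""How much reward does the task's true representation actually buy?

Simulates hybrid-value agents across a grid of the representation weight
w4 (0 = six separate states, 1 = the four shared states matching the task's
generative structure) and reports mean reward per trial.  The shared
representation speeds re-learning after each reversal, but the net reward
gain is small — the task exerts little pressure to learn its true structure.
"""

from odorchoice import reward_vs_w4

table, manifest = reward_vs_w4(n_sessions=100, seed=5)
print(table.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
r0 = table.mean_reward_per_trial.iloc[0]
r1 = table.mean_reward_per_trial.iloc[-1]
print(f"\nendpoint gap: {r1 - r0:+.4f} drops/trial "
      f"({(r1 - r0) / r0:+.1%} of the w4=0 level) — a modest payoff for "
      "adopting the true task structure.")
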