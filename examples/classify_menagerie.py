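"""Classify the canonical menagerie of Life patterns.

Each built-in fixture is simulated on the unbounded plane until its
initial shape recurs (or its fate-cycle is found). The printed kind,
period and displacement are the taxonomy of emergent forms: still lifes
persist unchanged, oscillators return in place after a cycle, spaceships
return displaced, and transients measure how long a shape takes to
settle (the L-tromino "adheres" into a block after one step).
"""

from lifelab import FIXTURE_NAMES, classify_exact, classify_fate, fixture

print(f"{'pattern':<12} {'exact kind':<12} {'fate kind':<12} "
      f"{'period':>6} {'displacement':>13} {'transient':>9}")
for name in FIXTURE_NAMES:
    pat = fixture(name)
    exact = classify_exact(pat, max_generations=1200)
    fate = classify_fate(pat, max_generations=1200)
    period = fate.period if fate.period is not None else "-"
    disp = str(fate.displacement) if fate.displacement else "-"
    print(f"{name:<12} {exact.kind:<12} {fate.kind:<12} "
          f"{period:>6} {disp:>13} {fate.transient:>9}")

print()
print("A '-' period means no recurrence was found within the budget: the")
print("R-pentomino splinters and launches gliders, so its global state")
print("never repeats on the unbounded plane.")
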