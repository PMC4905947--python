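"""Collide two gliders head-on and census the debris.

Two gliders on reciprocal courses are placed 11 cells apart. The outcome
is fully determined by the offset, yet nothing in the initial conditions
reveals it: destruction, transformation, or new stable forms. The
survivor census reports what is left once the global state cycles.
"""

from lifelab import Pattern, collide, fixture

se_glider = fixture("glider")
nw_glider = Pattern(frozenset((-x, -y) for x, y in se_glider.cells), name="glider-nw")

outcome = collide(se_glider, nw_glider, offset=(11, 11), max_generations=300)

print(f"offset: {outcome.offset}")
print(f"stabilized after {outcome.generations_to_stability} generations "
      f"(global period {outcome.period})")
print(f"final population: {outcome.population_final}")
print("survivor census:")
for rec in outcome.survivor_census.to_records():
    print(f"  {rec['count']} x {rec['kind']} (period {rec['period']})")
print("\nA deterministic but unpredictable outcome: the collision rules are")
print("three lines long, the debris is not computable without running them.")
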