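"""Karlin–Altschul statistics behind the e-value filter.

Shows the scale parameter lambda and prefactor K for the default scoring
scheme (+2/−3, gap 5+2L), and the alignment score a hit must reach for its
e-value to pass the 1e-4 cutoff in a typical search.
"""

from pannumt.karlin import ScoringScheme, karlin_k, solve_lambda

scheme = ScoringScheme()
print(f"default scheme: lambda={scheme.lambda_} K={scheme.K} "
      f"({scheme.source})")

lam = solve_lambda(2, -3)
print(f"ungapped lambda(+2,-3) = {lam:.6f}, K = {karlin_k(2, -3):.4f}")

m, n = 16_569, 2_000_000  # one mitogenome query vs a 2 Mb subject
s_star = scheme.score_cutoff(1e-4, m, n)
print(f"score needed for E <= 1e-4 at m={m}, n={n}: {s_star:.1f}")
print(f"  -> about {s_star / 2:.0f} matched bases; with the identity filter "
      "this is what makes ~28 bp the shortest reportable NUMT")
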