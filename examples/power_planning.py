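"""Sample-size planning and effect-size arithmetic on published group
summaries: the smallest-effect-of-interest design (d = 0.36) and the
TOST equivalence test's power."""

from searchprime import (
    GroupSummary,
    cohens_d_from_summaries,
    power_t,
    power_tost,
    welch_from_summaries,
)

n = power_t(0.36, alpha=0.05, target_power=0.95, alternative="greater")
print(f"one-sided t-test, d = 0.36, 95% power: n = {n} per condition")
print(f"TOST power at bounds d = +-0.36, n = {n}/arm, true effect 0: "
      f"{100 * power_tost(n, 0.36, 0.05, 0.0):.2f}%")

# effect-size engine on printed summaries (dispersion manipulation check)
g_clustered = GroupSummary(n=172, mean=9.95, sd=1.34)
g_dispersed = GroupSummary(n=167, mean=12.07, sd=1.71)
t = welch_from_summaries(g_clustered, g_dispersed)
d = cohens_d_from_summaries(g_clustered, g_dispersed)
print(f"manipulation check: Welch t({t.df:.1f}) = {t.statistic:.2f}, "
      f"d = {d.d:.2f}, CI95 [{d.ci_low:.2f}, {d.ci_high:.2f}]")

# |d| ~ 1.38: landscape type strongly changes how clustered the search is.
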