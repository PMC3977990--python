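"""Population attributable risk, power and control allele frequencies."""

import snpmeta as sm
from snpmeta.translation import PowerSpec

table = sm.load_table1()
for eth in (None, "Caucasian", "East Asian", "Indian"):
    fs = sm.control_freq_summary(table, eth)
    name = eth or "all studies"
    print(f"{name:>12}: control K-allele freq {fs.mean:.2f} "
          f"(95% CI {fs.ci_low:.2f}-{fs.ci_high:.2f}; "
          f"range {fs.minimum:.2f}-{fs.maximum:.2f}; k={fs.k})")

# Attributable risk from the published per-allele OR and the Caucasian
# weighted control frequency:
print(f"PAR at OR=1.12, freq=0.40: {sm.par(1.12, 0.40):.1%}")

# Sample size for 80% power at the ethnic-specific OR and frequency:
for name, p0, or_ in (("Caucasian", 0.40, 1.12), ("East Asian", 0.36, 1.13)):
    r = sm.sample_size_for_power(PowerSpec(p0=p0, or_per_allele=or_))
    print(f"{name}: {r.n_cases} case-control pairs (~{r.n_rounded}) "
          f"for 80% power at alpha=0.05")
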