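"""Two-site cohort comparison statistics from printed summary counts.

Uses the bundled example counts from a published two-site adolescent
cohort (N=186: New York 84, Pittsburgh 102) and reproduces the printed
test statistics: odds ratios oriented second-site-over-first, Yates-
corrected chi-square for 2x2 tables, Welch t from group summaries, and
Cramer's V in its df-normalised convention.
"""

from mobrisk import example_data as ex
from mobrisk.descriptives import (
    GroupSummary, chi_square, cohens_d, cramers_v, odds_ratio_2x2, welch_t,
)

for label, tbl, printed in [
    ("male sex", ex.SEX_BY_SITE, 1.77),
    ("MDD", ex.MDD_BY_SITE, 1.81),
    ("Hispanic ethnicity", ex.HISPANIC_BY_SITE, 0.14),
    ("substance use disorder", ex.SUD_BY_SITE, 0.24),
]:
    or_, _ = odds_ratio_2x2(tbl)
    print(f"OR {label:24s} {or_:6.3f}   (published {printed})")

chi2, df = chi_square(ex.SEX_BY_SITE)
print(f"\nchi2 sex x site (Yates)   {chi2:6.2f} df={df} (published 1.79)")
import warnings
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    chi2r, dfr = chi_square(ex.RACE_BY_SITE)
    v = cramers_v(ex.RACE_BY_SITE)
print(f"chi2 race x site          {chi2r:6.2f} df={dfr} (published 42.38)")
print(f"Cramer's V (df-normalised) {v['df_normalized']:.3f} (published 0.21); "
      f"standard convention {v['standard']:.3f}")

ny = GroupSummary(*ex.PAST_MONTH_IDEATION["NY"])
pitt = GroupSummary(*ex.PAST_MONTH_IDEATION["PITT"])
t, dfw = welch_t(ny, pitt)
print(f"\nWelch t past-month ideation {t:.3f} df={dfw:.1f} (published -2.15), "
      f"d = {cohens_d(ny, pitt):.3f}")
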