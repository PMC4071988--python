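"""Score studies on the five-category epidemiological quality rubric.

Each study earns 0-3 points for source of cases, source of controls,
genotyping specimen, Hardy-Weinberg equilibrium in controls, and total
sample size (max 15); a total of 10 or more marks a high-quality study.
The bundled characteristics table also carries the scores the original
reviewers reported, for comparison.
"""

from genemeta import load_fixture, load_study_characteristics, quality_score

chars = load_study_characteristics().set_index("study_id")
print(f"{'study':<10}{'computed':>9}{'reported':>9}  category points")
for study in load_fixture("rs861539").studies:
    score = quality_score(study.metadata)
    reported = chars.loc[study.study_id, "reported_quality"]
    print(f"{study.study_id:<10}{score.total:>9}{reported:>9}  {score.per_category}")
print(f"\nenrolled totals: {chars.total_cases.sum()} cases / {chars.total_controls.sum()} controls")
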