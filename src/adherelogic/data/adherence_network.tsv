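## Endocrine-therapy adherence decisional-logic circuit (synthetic transcription).
## 18 factors, 43 signed causal interactions. No machine-readable wiring for this
## clinical domain exists, so this edge list was assembled from well-established
## qualitative findings about endocrine-therapy adherence:
##   - side-effect burden erodes quality of life; its impact is buffered by
##     satisfaction with the healthcare team
##   - higher age, lower education, lower tumor stage, and poor health literacy
##     lower perceived recurrence risk
##   - fear of recurrence outweighs quality-of-life losses in the decision to stay
##     on treatment
##   - pill-taking routines and adherence reinforce each other (habit loop)
##   - discontinued patients report more coping deficits and weaker routines
## Context factors (age, education, household income, tumor stage) are inputs:
## they condition the logic but are never updated. All nodes are ternary
## (0 = low, 1 = nominal, 2 = high). The eight targetable nodes are the
## clinically actionable behavioral mediators.
# nodes
age	input	3	0
education	input	3	0
household_income	input	3	0
tumor_stage	input	3	0
adherence	dynamic	3	0
trust_in_physician	dynamic	3	1
provider_satisfaction	dynamic	3	0
treatment_cost_worry	dynamic	3	1
health_literacy	dynamic	3	1
numeracy	dynamic	3	0
quality_of_life	dynamic	3	1
coping_deficit	dynamic	3	1
general_anxiety	dynamic	3	1
recurrence_worry	dynamic	3	1
risk_perception	dynamic	3	0
side_effects	dynamic	3	0
comorbidities	dynamic	3	0
behavioral_routines	dynamic	3	1
# edges
side_effects	quality_of_life	-
side_effects	coping_deficit	+
side_effects	adherence	-
quality_of_life	adherence	+
quality_of_life	general_anxiety	-
risk_perception	adherence	+
risk_perception	recurrence_worry	+
recurrence_worry	adherence	+
recurrence_worry	general_anxiety	+
recurrence_worry	quality_of_life	-
general_anxiety	quality_of_life	-
general_anxiety	recurrence_worry	+
general_anxiety	behavioral_routines	-
trust_in_physician	adherence	+
trust_in_physician	provider_satisfaction	+
provider_satisfaction	trust_in_physician	+
provider_satisfaction	coping_deficit	-
provider_satisfaction	quality_of_life	+
coping_deficit	quality_of_life	-
coping_deficit	adherence	-
treatment_cost_worry	adherence	-
treatment_cost_worry	general_anxiety	+
behavioral_routines	adherence	+
adherence	side_effects	+
adherence	recurrence_worry	-
adherence	behavioral_routines	+
health_literacy	risk_perception	+
health_literacy	treatment_cost_worry	-
health_literacy	trust_in_physician	+
numeracy	risk_perception	+
comorbidities	quality_of_life	-
comorbidities	adherence	-
comorbidities	coping_deficit	+
age	risk_perception	-
age	comorbidities	+
age	behavioral_routines	+
education	health_literacy	+
education	numeracy	+
education	risk_perception	+
household_income	treatment_cost_worry	-
household_income	quality_of_life	+
tumor_stage	risk_perception	+
tumor_stage	recurrence_worry	+
# adherence adherence
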