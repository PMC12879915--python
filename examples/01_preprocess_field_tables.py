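"""Preprocess raw field tables: SG correction, sunrise anchoring, exclusions.

Builds a small synthetic study, then runs the preprocessing stage and prints
what it produces: the population specific gravity used for correction, the
exclusion log, and the first few model-ready observations.
"""

from cortrhythm import (default_study_config, default_truth, generate_dataset,
                        prepare_model_data)

study = default_study_config()
truth = default_truth(seed=1, n_participants=20, n_pregnant=2,
                      n_missing_age=1, n_incomplete_questionnaire=1)
samples, participants, questionnaire, _ = generate_dataset(truth, study)

data, exclusions = prepare_model_data(samples, participants, questionnaire,
                                      study, model_stage="model0")

print(f"enrolled participants : {len(participants)}")
print(f"analyzable (model 0)  : {data.n_participants}")
print(f"urine samples         : {data.n_samples}")
print(f"population SG target  : {data.meta['sg_target']:.4f}")
print("\nexclusion log:")
print(exclusions.to_string(index=False))
print("\nfirst five observations (corrected pg/mL, hours since sunrise):")
for y, t in list(zip(data.y, data.rel_time_h))[:5]:
    print(f"  {y:12.0f}  at t = {t:5.2f} h")
# Corrected cortisol rescales each raw value by (SG_target-1)/(SG_sample-1);
# rel_time 0 marks first-morning voids anchored at sunrise.
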