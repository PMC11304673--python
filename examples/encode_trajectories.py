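"""Encode disease onset times into fractional-time 4-tuples.

A participant's cardiometabolic continuum is the 4-tuple
(t_HYP, t_DM, t_HD, t_STK): each onset time divided by the follow-up
duration, 1 when the disease never occurred.
"""

from cmcpatterns import DiseaseCode, EventRecord, encode_trajectory, first_disease, pattern_string

# hypertension after 2 years, diabetes after 4, in a 10-year follow-up
traj = encode_trajectory(
    [EventRecord(DiseaseCode.HYP, 2.0, 10.0), EventRecord(DiseaseCode.DM, 4.0, 10.0)],
    follow_up=10.0,
    participant_id="example-1",
)
print("4-tuple:", traj.times)                  # (0.2, 0.4, 1.0, 1.0)
print("ordered pattern:", pattern_string(traj))  # HYP→DM: hypertension first, then diabetes
print("first disease:", first_disease(traj)[0].label)

# a disease-free participant encodes to all ones
healthy = encode_trajectory([], follow_up=12.0, participant_id="example-2")
print("disease-free:", healthy.times, "->", pattern_string(healthy))
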