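# Preferred terms treated as symptom/descriptor recordings rather than
# anatomic diagnoses.  A low-grade event whose member terms all come from
# this list, with no hospitalization, medication change, or anatomic
# diagnosis, is adjudicated not-an-event.
Angina pectoris
Anginal equivalent
Cardiac discomfort
Chest discomfort
Chest pain
Clumsiness
Dysarthria
Intermittent claudication
Ischaemic limb pain
Non-cardiac chest pain
Peripheral coldness
Poor peripheral circulation
Dependent rubor
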