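# Cardiac-failure screening terms (editable stand-in for the proprietary
# Cardiac Failure SMQ; contains the heart-failure preferred terms that the
# screen must widen to cover).
Cardiac failure
Cardiac failure congestive
Cardiac failure acute
Cardiac failure chronic
Cardiogenic shock
Left ventricular failure
Right ventricular failure
Ventricular failure
Acute left ventricular failure
Acute right ventricular failure
Cardiopulmonary failure
Ejection fraction decreased
Pulmonary oedema
Acute pulmonary oedema
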