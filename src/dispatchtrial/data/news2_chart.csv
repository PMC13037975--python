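# NEWS 2 scoring chart (Royal College of Physicians, 2017), SpO2 Scale 1.
# kind=range rows: closed interval [lo, hi] on the component's native grid
# (integers for respiratory_rate/spo2/systolic_bp/pulse, 0.1 degC for temperature).
# kind=category rows: exact label match.
component,kind,lo,hi,category,points
respiratory_rate,range,0,8,,3
respiratory_rate,range,9,11,,1
respiratory_rate,range,12,20,,0
respiratory_rate,range,21,24,,2
respiratory_rate,range,25,60,,3
spo2,range,50,91,,3
spo2,range,92,93,,2
spo2,range,94,95,,1
spo2,range,96,100,,0
on_oxygen,category,,,False,0
on_oxygen,category,,,True,2
systolic_bp,range,40,90,,3
systolic_bp,range,91,100,,2
systolic_bp,range,101,110,,1
systolic_bp,range,111,219,,0
systolic_bp,range,220,300,,3
pulse,range,20,40,,3
pulse,range,41,50,,1
pulse,range,51,90,,0
pulse,range,91,110,,1
pulse,range,111,130,,2
pulse,range,131,220,,3
consciousness,category,,,Alert,0
consciousness,category,,,Confusion,3
consciousness,category,,,Voice,3
consciousness,category,,,Pain,3
consciousness,category,,,Unresponsive,3
temperature,range,30.0,35.0,,3
temperature,range,35.1,36.0,,1
temperature,range,36.1,38.0,,0
temperature,range,38.1,39.0,,1
temperature,range,39.1,43.0,,2
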