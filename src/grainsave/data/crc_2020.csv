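category,amount
Allied health and other services,0.3
General practitioner services,15.0
Medical imaging,3.3
Pathology,3.8
Pharmaceutical benefits scheme,129.6
Private hospital services,222.2
Public hospital admitted patient,191.9
Public hospital emergency department,0.6
Public hospital outpatient,116.8
Specialist services,45.4
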