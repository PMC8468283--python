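category,amount
Allied health and other services,0.3
General practitioner services,13.2
Medical imaging,2.9
Pathology,3.3
Pharmaceutical benefits scheme,113.8
Private hospital services,195.2
Public hospital admitted patient,168.6
Public hospital emergency department,0.5
Public hospital outpatient,102.6
Specialist services,39.9
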