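category,amount
Allied health and other services,5.0
General practitioner services,303.1
Medical imaging,93.6
Pathology,137.4
Pharmaceutical benefits scheme,1285.1
Private hospital services,2318.0
Public hospital admitted patient,2103.8
Public hospital emergency department,28.9
Public hospital outpatient,949.0
Specialist services,684.8
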