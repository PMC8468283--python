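category,amount
Allied health and other services,5.7
General practitioner services,345.0
Medical imaging,106.5
Pathology,156.5
Pharmaceutical benefits scheme,1462.8
Private hospital services,2638.5
Public hospital admitted patient,2394.7
Public hospital emergency department,32.9
Public hospital outpatient,1080.2
Specialist services,779.5
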