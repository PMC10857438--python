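# Milan testbed: core motion (M*) and door (D*) sensors by room.
M012	Kitchen	motion
M014	Kitchen	motion
M015	Kitchen	motion
M016	Kitchen	motion
M022	Kitchen	motion
M023	Kitchen	motion
D003	Kitchen	door
M006	Living room	motion
M008	Living room	motion
M026	Living room	motion
M019	Bedroom 1	motion
M020	Bedroom 1	motion
M021	Bedroom 1	motion
M028	Bedroom 1	motion
M024	Bedroom 2	motion
M013	Bathroom 1	motion
M025	Bathroom 1	motion
M017	Bathroom 2	motion
M018	Bathroom 2	motion
M003	Dining	motion
M027	Dining	motion
M007	Office	motion
M010	Hall 1	motion
M011	Hall 1	motion
M009	Hall 2	motion
M001	Front door	motion
M002	Front door	motion
D001	Front door	door
D002	Front door	door
M004	Reading room	motion
M005	Reading room	motion
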