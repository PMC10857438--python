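# Aruba testbed: motion (M*) and door (D*) sensors by room.
M015	Kitchen	motion
M016	Kitchen	motion
M017	Kitchen	motion
M018	Kitchen	motion
M019	Kitchen	motion
M009	Living room	motion
M010	Living room	motion
M012	Living room	motion
M013	Living room	motion
M020	Living room	motion
M001	Bedroom 1	motion
M002	Bedroom 1	motion
M003	Bedroom 1	motion
M005	Bedroom 1	motion
M006	Bedroom 1	motion
M007	Bedroom 1	motion
M023	Bedroom 2	motion
M024	Bedroom 2	motion
D003	Bathroom 1	door
M029	Bathroom 1	motion
M031	Bathroom 1	motion
M004	Bathroom 2	motion
M014	Dining	motion
M025	Office	motion
M026	Office	motion
M027	Office	motion
M028	Office	motion
M008	Hall 1	motion
M021	Hall 2	motion
M022	Hall 2	motion
M011	Front door	motion
D001	Front door	door
D002	Back door	door
M030	Garage door	motion
D004	Garage door	door
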