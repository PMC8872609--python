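code	name	segment
R1	An insufficient estimate of the amount needed to collect	Reception
R2	Getting inadequate or incorrect clinical information in the application form	Reception
R3	Unavailability of some blood donation centres	Reception
R4	Decreased blood donor satisfaction	Reception
R5	Software problems	Reception
R6	Differences in the quality of products produced by different blood transfusion centres	Reception
R7	Congestion and rush to donate blood	Reception
R8	Failure of donor screening	Medical consultation and examination
R9	Gathering incorrect information from a donor	Medical consultation and examination
R10	Lack of quality and safety during blood donation	Blood donation
R11	Equipment failure	Blood donation
R12	Mismatch	Blood donation
R13	Wastes and losses	Blood donation
R14	Non-calibrated equipment	Blood donation
R15	The temperature change of the blood bags	Blood donation
R16	Late delivery	Blood donation
R17	Decreased blood quality during transportation	Other provinces
R18	Delay in receiving blood	Other provinces
R19	Getting poor quality blood	Other provinces
R20	Failure to perform preventive maintenance	Maintenance
R21	Temperature changes	Producing production
R22	Equipment failure	Producing production
R23	Non-calibrated equipment	Producing production
R24	Software and system problems	Producing production
R25	Sources likely to be compromised following an autoclave explosion	Producing production
R26	Expiration of products	Producing production
R27	Error in confirming the blood group	Test
R28	Undetectable new viruses	Test
R29	Incorrect confirmation of the sample	Test
R30	Unsafe disposal of positive units	Test
R31	Error in data entry	Test
R32	Temperature changes	Test
R33	Non-calibrated equipment	Test
R34	Equipment failure	Test
R35	Improper blood inventory level	Blood products storage
R36	Shortage of emergency storage units	Blood products storage
R37	Insecure disposal of expired units	Blood products storage
R38	Blood rotting	Blood products storage
R39	Expiration of blood products	Blood products storage
R40	An insufficient response to the hospital demand	Distribution
R41	Delivering wrong blood bag	Distribution
R42	Improper blood supply (life expectancy)	Distribution
R43	Improper allocation of blood to different centres (in terms of units)	Distribution
R44	Non-standard packaging on delivery	Distribution
R45	Delays in shipping	Distribution
R46	Equipment failure	Distribution
R47	Decreased blood quality during transportation	Distribution
R48	Product corruption	Warehouse
R49	Lack of materials and equipment (such as kits and bags)	Warehouse
R50	Excessive items	Warehouse
R51	A mistake in blood compatibility test	Hospitals
R52	Delay in the use of allocated blood bags	Hospitals
R53	Waiting for the blood reserved by doctors	Hospitals
R54	Insufficient blood inventory level	Hospitals
R55	Improper disposal of expired units or wastes	Hospitals
R56	Inappropriate assessment of the amount of blood required before surgery	Hospitals
R57	Blood rotting	Hospitals
R58	Temperature changes	Hospitals
R59	Side effects of blood transfusion	Hospitals
R60	Cumbersome rules (such as customs rules)	Government
R61	Lack of proper budget allocation	Government
R62	Economic and political effects of sanctions	Government
R63	Changes in the exchange rate	Government
R64	Inflation	Government
R65	Energy rate changes	Government
R66	Financial crises	Government
R67	Selection of inappropriate suppliers	Suppliers
R68	Delay in dispatch	Suppliers
R69	Purchase of inappropriate equipment	Suppliers
R70	Cut-off relationships with suppliers	Suppliers
R71	Inappropriate contracts	Suppliers
R72	Inappropriate public education	Education and training administration
R73	Inaccurate and false information and false excitement	Broadcasting organization and cyberspace
R74	Improper implementation of standards	Certificate companies
R75	Error in checking tests	QC
R76	Inadequate quality control of materials	QC
R77	Improper quality control of products	QC
R78	Failure to identify discrepancies in the audit	QC
R79	Not paying attention to the documentation revision	QC
R80	Not paying attention to the process of quality assurance system development	QC
R81	Incorrect conduct of validation studies	QC
R82	Unauthorized access to organizational information	IT
R83	Cyber-attacks and hacking	IT
R84	Failure to server data recovery	IT
R85	Lack of data transfer between different systems	IT
R86	Power outage	Environment
R87	Earthquake	Environment
R88	Fire	Environment
R89	Contagious events	Environment
R90	Severe climate change	Environment
R91	Emerging diseases	Environment
R92	Changing culture and lifestyle	Society
R93	Street chaos	Society
R94	Terrorist attacks	Terrorist groups
R95	War	Terrorist groups
R96	Safety negligence	Human resources
R97	Incompatibility of human resources with the goals of the organization	Human resources
R98	Low productivity of the employees	Human resources
R99	Strike	Human resources
R100	Not paying attention to standards and validations	Human resources
R101	Lack of succession	Human resources
R102	Not saving the knowledge of human resources	Human resources
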