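An elderly patient suffering dementia stayed indoors. Doctors reviewed thick charts beneath humming ceiling fans. Corridors smelled faintly like disinfectant each weekday morning. Orderlies wheeled squeaking trolleys past crowded waiting rooms.
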